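"""Cross-cohort replication of per-CpG associations.

Each CpG-trait comparison between a local and a reference summary table is
classified by confidence-interval overlap and effect direction into one of
three classes that partition all records:

* ``overlap`` — the two CIs intersect (the association replicates);
* ``consistent_nonoverlap`` — CIs disjoint but effect signs agree;
* ``opposite`` — CIs disjoint and effect signs disagree.

Discordant records can be annotated with genetic context (mQTLs, population
minor-allele-frequency gaps, polymorphic/cross-reactive probe flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ewasrep.varpower import lmg_shares, nested_lrt

logger = logging.getLogger(__name__)

DIRECTION_CLASSES = ("overlap", "consistent_nonoverlap", "opposite")

FLAG_COLUMNS = (
    "polymorphic_probe",
    "cross_reactive",
    "has_cis_mqtl",
    "has_trans_mqtl",
    "maf_discordant",
)


@dataclass
class ComparisonResult:
    """Per-probe comparison records plus the probes present in only one table."""

    records: pd.DataFrame
    unmatched_local: pd.DataFrame
    unmatched_reference: pd.DataFrame
    level: float = 0.95


@dataclass
class TraitConcordanceSummary:
    trait: str
    ancestry: str
    n_tests: int
    n_overlap: int
    n_consistent: int
    n_opposite: int
    frac_overlap: float
    frac_consistent: float
    frac_opposite: float
    slope: float | None = None
    slope_se: float | None = None
    slope_p: float | None = None
    r_squared: float | None = None

    def __post_init__(self):
        if self.n_overlap + self.n_consistent + self.n_opposite != self.n_tests:
            raise ValueError("direction classes must partition the record set")

    @property
    def pct_overlap(self) -> int:
        return round(100.0 * self.frac_overlap)

    @property
    def pct_consistent(self) -> int:
        return round(100.0 * self.frac_consistent)

    @property
    def pct_opposite(self) -> int:
        return round(100.0 * self.frac_opposite)


@dataclass
class GeneticAnnotation:
    """User-supplied genetic context tables.

    ``mqtl``: columns probe_id, snp_id, type ("cis"/"trans"), z.
    ``maf``: columns snp_id, population, maf (long format, maf in [0, 0.5]).
    ``flags``: columns probe_id, flag ("polymorphic"/"cross_reactive").
    """

    mqtl: pd.DataFrame
    maf: pd.DataFrame
    flags: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["probe_id", "flag"]))

    def __post_init__(self):
        if len(self.maf):
            vals = self.maf["maf"].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 0.5)):
                raise ValueError("minor allele frequencies must lie in [0, 0.5]")


def _ci_bounds(effect: np.ndarray, se: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    q = float(stats.norm.ppf(0.5 + level / 2.0))
    return effect - q * se, effect + q * se


def classify_directions(
    local_effect: np.ndarray,
    local_lo: np.ndarray,
    local_hi: np.ndarray,
    ref_effect: np.ndarray,
    ref_lo: np.ndarray,
    ref_hi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (overlap flags, direction classes) for paired intervals.

    Overlap iff ``max(lo_a, lo_b) <= min(hi_a, hi_b)``.  A zero effect is
    treated as directionally consistent with either sign.
    """
    overlap = np.maximum(local_lo, ref_lo) <= np.minimum(local_hi, ref_hi)
    same_sign = (np.sign(local_effect) * np.sign(ref_effect)) >= 0
    direction = np.where(
        overlap, "overlap", np.where(same_sign, "consistent_nonoverlap", "opposite")
    )
    return overlap, direction


def compare_associations(
    local: pd.DataFrame,
    reference: pd.DataFrame,
    level: float = 0.95,
) -> ComparisonResult:
    """Compare two summary tables probe by probe.

    Tables are inner-joined on ``probe_id``; probes found in only one table
    are reported in the result's ``unmatched_*`` frames rather than silently
    dropped.  CIs are rebuilt from effect and SE at ``level`` using the
    normal quantile so both cohorts are treated identically.
    """
    ori_a = local.attrs.get("orientation")
    ori_b = reference.attrs.get("orientation")
    if ori_a is not None and ori_b is not None and ori_a != ori_b:
        raise ValueError(
            f"orientation mismatch between tables: {ori_a!r} vs {ori_b!r}"
        )
    merged = local.merge(
        reference, on="probe_id", how="inner", suffixes=("_local", "_ref")
    )
    unmatched_local = local[~local["probe_id"].isin(merged["probe_id"])]
    unmatched_reference = reference[~reference["probe_id"].isin(merged["probe_id"])]

    le = merged["effect_local"].to_numpy(dtype=float)
    re_ = merged["effect_ref"].to_numpy(dtype=float)
    l_lo, l_hi = _ci_bounds(le, merged["se_local"].to_numpy(dtype=float), level)
    r_lo, r_hi = _ci_bounds(re_, merged["se_ref"].to_numpy(dtype=float), level)
    overlap, direction = classify_directions(le, l_lo, l_hi, re_, r_lo, r_hi)

    records = pd.DataFrame(
        {
            "probe_id": merged["probe_id"],
            "trait": merged.get("trait_local", merged.get("trait", pd.Series(dtype=object))),
            "local_effect": le,
            "local_se": merged["se_local"],
            "local_ci_low": l_lo,
            "local_ci_high": l_hi,
            "ref_effect": re_,
            "ref_se": merged["se_ref"],
            "ref_ci_low": r_lo,
            "ref_ci_high": r_hi,
            "ref_ancestry": merged.get("ancestry_ref", merged.get("ancestry", "NA")),
            "overlap": overlap,
            "direction_class": direction,
        }
    )
    for col in FLAG_COLUMNS:
        records[col] = False
    # partition identity is asserted on every run
    counts = records["direction_class"].value_counts()
    assert int(counts.sum()) == len(records)
    return ComparisonResult(
        records=records,
        unmatched_local=unmatched_local.reset_index(drop=True),
        unmatched_reference=unmatched_reference.reset_index(drop=True),
        level=level,
    )


COMPARISON_TABLE_COLUMNS = (
    "trait",
    "ancestry",
    "probe_id",
    "local_effect",
    "local_se",
    "ref_effect",
    "ref_se",
)


def classify_comparison_table(table: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Classify a long-format table of paired per-CpG statistics.

    Expects one row per CpG-trait-ancestry comparison with columns
    ``trait, ancestry, probe_id, local_effect, local_se, ref_effect,
    ref_se``; returns a copy with rebuilt CI bounds plus ``overlap`` and
    ``direction_class`` columns.  This is the ingestion path for externally
    published paired summary statistics.
    """
    missing = [c for c in COMPARISON_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"comparison table lacks required columns: {missing}")
    out = table.copy()
    le = out["local_effect"].to_numpy(dtype=float)
    re_ = out["ref_effect"].to_numpy(dtype=float)
    l_lo, l_hi = _ci_bounds(le, out["local_se"].to_numpy(dtype=float), level)
    r_lo, r_hi = _ci_bounds(re_, out["ref_se"].to_numpy(dtype=float), level)
    overlap, direction = classify_directions(le, l_lo, l_hi, re_, r_lo, r_hi)
    out["local_ci_low"], out["local_ci_high"] = l_lo, l_hi
    out["ref_ci_low"], out["ref_ci_high"] = r_lo, r_hi
    out["overlap"] = overlap
    out["direction_class"] = direction
    return out


def summarize_trait(
    records: pd.DataFrame,
    include_regression: bool = True,
) -> TraitConcordanceSummary:
    """Summarize one trait/ancestry slice of comparison records."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record set")
    traits = records["trait"].unique()
    ancestries = records["ref_ancestry"].unique()
    if len(traits) > 1 or len(ancestries) > 1:
        raise ValueError("records must share a single trait and ancestry")
    n = len(records)
    counts = records["direction_class"].value_counts()
    n_overlap = int(counts.get("overlap", 0))
    n_consistent = int(counts.get("consistent_nonoverlap", 0))
    n_opposite = int(counts.get("opposite", 0))
    summary = TraitConcordanceSummary(
        trait=str(traits[0]),
        ancestry=str(ancestries[0]),
        n_tests=n,
        n_overlap=n_overlap,
        n_consistent=n_consistent,
        n_opposite=n_opposite,
        frac_overlap=n_overlap / n,
        frac_consistent=n_consistent / n,
        frac_opposite=n_opposite / n,
    )
    if include_regression and n >= 3:
        res = _effect_regression(
            records["local_effect"].to_numpy(), records["ref_effect"].to_numpy()
        )
        summary.slope, summary.slope_se, summary.slope_p, summary.r_squared = res[:4]
    return summary


@dataclass
class EffectRegression:
    slope: float
    se: float
    p: float
    r_squared: float
    n: int
    y_axis: str
    intercept: float
    p_slope_eq_1: float


def _effect_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float, float]:
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - 2
    tss = float(np.sum((y - y.mean()) ** 2))
    xx = float(np.sum((x - x.mean()) ** 2))
    se = np.sqrt(rss / df / xx) if df > 0 and xx > 0 else 0.0
    slope = float(coef[1])
    if se > 0:
        p = float(2.0 * stats.t.sf(abs(slope / se), df))
        p1 = float(2.0 * stats.t.sf(abs((slope - 1.0) / se), df))
    else:
        p = 0.0 if slope != 0 else 1.0
        p1 = 0.0 if slope != 1.0 else 1.0
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return slope, float(se), p, float(r2), float(coef[0]), p1


def effect_size_regression(
    local: pd.DataFrame,
    reference: pd.DataFrame,
    y_axis: str = "reference",
) -> EffectRegression:
    """OLS (with intercept) of one cohort's effect sizes on the other's.

    By default the reference effects are regressed on the local effects
    (y = reference, x = local); set ``y_axis='local'`` for the other
    convention.  The p-value tests slope = 0 two-sided; a slope = 1 test is
    reported alongside.
    """
    if y_axis not in ("reference", "local"):
        raise ValueError("y_axis must be 'reference' or 'local'")
    merged = local.merge(reference, on="probe_id", how="inner", suffixes=("_local", "_ref"))
    if len(merged) < 3:
        raise ValueError(f"effect-size regression needs >= 3 shared probes; got {len(merged)}")
    x = merged["effect_local" if y_axis == "reference" else "effect_ref"].to_numpy(dtype=float)
    y = merged["effect_ref" if y_axis == "reference" else "effect_local"].to_numpy(dtype=float)
    slope, se, p, r2, intercept, p1 = _effect_regression(x, y)
    return EffectRegression(
        slope=slope, se=se, p=p, r_squared=r2, n=len(merged), y_axis=y_axis,
        intercept=intercept, p_slope_eq_1=p1,
    )


def annotate_genetic_context(
    records: pd.DataFrame,
    annotation: GeneticAnnotation,
    maf_gap_threshold: float = 0.10,
    populations: tuple[str, str] = ("AFR", "EUR"),
) -> tuple[pd.DataFrame, dict]:
    """Set genetic-context flags on comparison records.

    ``maf_discordant`` is set when any SNP linked to the probe through the
    mQTL table has an absolute MAF difference >= ``maf_gap_threshold``
    between the two named populations.  Returns the annotated copy plus a
    summary of flag counts among opposite-direction records.
    """
    present = set(annotation.maf["population"].unique()) if len(annotation.maf) else set()
    for pop in populations:
        if pop not in present:
            raise KeyError(f"population {pop!r} absent from the MAF table")
    wide = annotation.maf.pivot_table(index="snp_id", columns="population", values="maf")
    gap = (wide[populations[0]] - wide[populations[1]]).abs()
    discordant_snps = set(gap[gap >= maf_gap_threshold].index)

    out = records.copy()
    mqtl = annotation.mqtl
    cis_probes = set(mqtl.loc[mqtl["type"] == "cis", "probe_id"])
    trans_probes = set(mqtl.loc[mqtl["type"] == "trans", "probe_id"])
    probe_snps = mqtl.groupby("probe_id")["snp_id"].agg(set)
    flagged_maf = {
        probe for probe, snps in probe_snps.items() if snps & discordant_snps
    }
    poly = set(annotation.flags.loc[annotation.flags["flag"] == "polymorphic", "probe_id"])
    xreact = set(
        annotation.flags.loc[annotation.flags["flag"] == "cross_reactive", "probe_id"]
    )

    pid = out["probe_id"]
    out["has_cis_mqtl"] = pid.isin(cis_probes)
    out["has_trans_mqtl"] = pid.isin(trans_probes)
    out["maf_discordant"] = pid.isin(flagged_maf)
    out["polymorphic_probe"] = pid.isin(poly)
    out["cross_reactive"] = pid.isin(xreact)

    opposite = out[out["direction_class"] == "opposite"]
    summary = {
        "n_opposite": int(len(opposite)),
        **{flag: int(opposite[flag].sum()) for flag in FLAG_COLUMNS},
    }
    return out, summary


def variance_explained_column(
    meth: pd.DataFrame,
    pheno: pd.DataFrame,
    spec,
    probe_set,
    surrogates=None,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-probe variance bookkeeping for a report table.

    For each probe: the exposure's relative-importance share of the outcome
    variance (x100), the full model's R-squared (x100), and the chi-square
    p-value comparing the model with and without the exposure.  Covariate
    blocks may be grouped into single predictors for the relative-importance
    enumeration via ``groups``; by default surrogate variables form one group
    and cell-fraction columns another.
    """
    from ewasrep.ewas import build_design

    design, exposure_name = build_design(pheno, spec, surrogates)
    samples = design.index
    X = design.drop(columns=["intercept"])

    if groups is None:
        groups = {}
        sv_cols = [c for c in X.columns if c.startswith("sv")]
        if sv_cols:
            groups["surrogates"] = sv_cols
        from ewasrep.synthetic import CELL_TYPES

        cell_cols = [c for c in X.columns if c in CELL_TYPES]
        if cell_cols:
            groups["cell_counts"] = cell_cols
    grouped_cols = {c for cols in groups.values() for c in cols}
    full_groups = {c: [c] for c in X.columns if c not in grouped_cols}
    full_groups.update(groups)

    reduced = X.drop(columns=[exposure_name])
    rows = []
    for probe in probe_set:
        y = meth.loc[probe, samples].to_numpy(dtype=float)
        decomp = lmg_shares(y, X, groups=full_groups)
        chi2, dof, p = nested_lrt(y, X, reduced)
        rows.append(
            {
                "probe_id": probe,
                "pct_var_exposure": 100.0 * decomp.shares[exposure_name],
                "pct_var_total": 100.0 * decomp.total_r2,
                "lrt_chi2": chi2,
                "lrt_df": dof,
                "lrt_p": p,
            }
        )
    return pd.DataFrame(rows)
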