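"""Per-CpG linear association models with surrogate-variable adjustment.

Models are ordinary least squares per probe, in either orientation:
methylation as outcome (effect = beta-value change per trait unit) or trait
as outcome (effect = trait units per beta-value).  Surrogate variables are
estimated from the residual structure of the methylation matrix by SVD with
a permutation-based choice of the number of components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: two-sided normal quantile for the default 95% interval
Z95 = 1.959964

SMALLEST_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class ModelSpec:
    """Description of one per-CpG association model."""

    trait: str
    orientation: Literal["methylation_outcome", "trait_outcome"] = "methylation_outcome"
    covariates: tuple[str, ...] = ()
    exposure_coding: Literal["continuous", "current_vs_never", "ever_vs_never"] = "continuous"
    n_surrogates: int | Literal["auto"] = 0
    trait_transform: Literal["identity", "log"] = "identity"

    def __post_init__(self):
        if self.orientation == "trait_outcome" and self.exposure_coding != "continuous":
            raise ValueError("trait_outcome orientation requires a continuous trait")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def model_id(self) -> str:
        side = "meth~" if self.orientation == "methylation_outcome" else f"{self.trait}~meth+"
        terms = [self.trait] if self.orientation == "methylation_outcome" else []
        terms += list(self.covariates)
        return side + "+".join(terms) if terms else side.rstrip("~+")


@dataclass
class SurrogateSet:
    """Orthonormal sample-space surrogate variables."""

    vectors: pd.DataFrame  # samples x k
    k: int
    method: str
    n_perm: int
    seed: int | None

    def __post_init__(self):
        if self.k != self.vectors.shape[1]:
            raise ValueError("k does not match the number of surrogate columns")
        if self.k > 0:
            gram = self.vectors.to_numpy().T @ self.vectors.to_numpy()
            if not np.allclose(gram, np.eye(self.k), atol=1e-8):
                raise ValueError("surrogate columns are not orthonormal")


def _exposure_vector(pheno: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    if spec.trait not in pheno.columns:
        raise KeyError(f"trait {spec.trait!r} not present in the phenotype table")
    raw = pheno[spec.trait]
    if spec.exposure_coding == "continuous":
        x = raw.astype(float)
        if spec.trait_transform == "log":
            if (x <= 0).any():
                raise ValueError(f"log transform requires strictly positive {spec.trait!r}")
            x = np.log(x)
    elif spec.exposure_coding == "current_vs_never":
        x = raw.where(raw.isin(["current", "never"]))
        x = (x == "current").astype(float).where(x.notna())
    elif spec.exposure_coding == "ever_vs_never":
        x = (raw != "never").astype(float)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown exposure coding {spec.exposure_coding!r}")
    return pd.Series(np.asarray(x, dtype=float), index=pheno.index, name=spec.trait)


def _covariate_frame(pheno: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols: list[pd.Series | pd.DataFrame] = []
    for name in covariates:
        if name == "cell_counts":
            from ewasrep.synthetic import CELL_TYPES

            present = [c for c in CELL_TYPES if c in pheno.columns]
            if len(present) < 2:
                raise KeyError("cell_counts covariate requires cell-fraction columns")
            # fractions sum to 1: drop the largest compartment to keep full rank
            cols.append(pheno[present].drop(columns=["Gran"], errors="ignore"))
            continue
        if name not in pheno.columns:
            raise KeyError(f"covariate {name!r} not present in the phenotype table")
        col = pheno[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(col.astype(float))
    if not cols:
        return pd.DataFrame(index=pheno.index)
    return pd.concat(cols, axis=1)


def build_design(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    surrogates: SurrogateSet | None = None,
) -> tuple[pd.DataFrame, str]:
    """Assemble the complete-case design matrix (with intercept).

    Returns the design and the name of the exposure column.  For
    ``trait_outcome`` orientation the exposure column is filled per probe by
    the caller; here it holds the (transformed) trait used as outcome.
    """
    exposure = _exposure_vector(pheno, spec)
    covar = _covariate_frame(pheno, spec.covariates)
    design = pd.concat([exposure, covar], axis=1)
    if surrogates is not None and surrogates.k > 0:
        sv = surrogates.vectors.reindex(design.index)
        design = pd.concat([design, sv], axis=1)
    design = design.dropna()
    for col in design.columns:
        if design[col].isna().all():
            raise ValueError(f"covariate {col!r} is entirely missing")
    design.insert(0, "intercept", 1.0)
    _check_full_rank(design)
    return design, exposure.name


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column for the error message
        keep: list[int] = []
        bad: list[str] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                keep.append(j)
            else:
                bad.append(str(design.columns[j]))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def estimate_surrogates(
    meth: pd.DataFrame,
    pheno: pd.DataFrame,
    spec: ModelSpec,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    max_k: int = 10,
) -> SurrogateSet:
    """Estimate surrogate variables from the methylation residual structure.

    Two-step procedure: regress each probe on exposure + covariates, take the
    row-centred residual matrix, and compare its leading singular-value
    variance shares against a permutation null (each probe's residuals
    permuted independently across samples, ``n_perm`` times).  Components
    significant at ``alpha`` — counted from the top until the first
    non-significant one — are returned as re-orthonormalized right-singular
    vectors.  With ``spec.n_surrogates`` set to a fixed integer the
    permutation step is skipped.
    """
    design, _ = build_design(pheno, spec)
    samples = design.index
    Y = meth[samples].to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n = len(samples)
    if n <= X.shape[1] + 2:
        raise ValueError("too few complete-case samples for surrogate estimation")

    hat = X @ np.linalg.solve(X.T @ X, X.T)
    resid = Y - Y @ hat.T
    resid = resid - resid.mean(axis=1, keepdims=True)

    U, s, Vt = np.linalg.svd(resid, full_matrices=False)
    shares = s**2 / np.sum(s**2)

    if isinstance(spec.n_surrogates, int):
        k = spec.n_surrogates
        if k > Vt.shape[0]:
            raise ValueError(f"requested {k} surrogates but only {Vt.shape[0]} available")
        method = "fixed"
    else:
        rng = np.random.default_rng(seed)
        kmax = min(max_k, len(s) - 1)
        exceed = np.zeros(kmax)
        for _ in range(n_perm):
            perm = rng.permuted(resid, axis=1)
            perm = perm - perm.mean(axis=1, keepdims=True)
            ps = np.linalg.svd(perm, compute_uv=False)
            pshares = ps**2 / np.sum(ps**2)
            exceed += pshares[:kmax] >= shares[:kmax]
        pvals = (exceed + 1) / (n_perm + 1)
        k = 0
        for i in range(kmax):
            if pvals[i] < alpha:
                k += 1
            else:
                break
        method = f"permutation(alpha={alpha})"

    vectors = Vt[:k].T if k > 0 else np.empty((n, 0))
    if k > 0:
        vectors, _ = np.linalg.qr(vectors)
    sv = pd.DataFrame(vectors, index=samples, columns=[f"sv{i+1}" for i in range(k)])
    return SurrogateSet(vectors=sv, k=k, method=method, n_perm=n_perm, seed=seed)


def _summary_frame(
    probe_ids: np.ndarray,
    effect: np.ndarray,
    se: np.ndarray,
    df: np.ndarray | int,
    spec: ModelSpec,
    n_used: int,
    cohort: str,
    ancestry: str,
    ci_level: float,
    ci_method: str,
) -> pd.DataFrame:
    # perfect fits leave numerically-zero residual variance
    degenerate = se <= 100 * np.finfo(float).eps * (np.abs(effect) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.where(degenerate, SMALLEST_P, p)
    p = np.clip(p, SMALLEST_P, 1.0)
    if ci_method == "normal":
        q = Z95 if ci_level == 0.95 else float(stats.norm.ppf(0.5 + ci_level / 2.0))
    elif ci_method == "t":
        q = stats.t.ppf(0.5 + ci_level / 2.0, df)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    table = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "trait": spec.trait,
            "cohort": cohort,
            "ancestry": ancestry,
            "n": n_used,
            "effect": effect,
            "se": se,
            "p": p,
            "ci_low": effect - q * se,
            "ci_high": effect + q * se,
            "model_id": spec.model_id,
            "degenerate": degenerate,
        }
    )
    table.attrs["orientation"] = spec.orientation
    table.attrs["ci_level"] = ci_level
    return table


def fit_ewas(
    meth: pd.DataFrame,
    pheno: pd.DataFrame,
    spec: ModelSpec,
    surrogates: SurrogateSet | None = None,
    cohort: str = "local",
    ancestry: str = "NA",
    ci_level: float = 0.95,
    ci_method: str = "normal",
) -> pd.DataFrame:
    """Fit the per-probe association model and return a summary table.

    Complete-case analysis: samples missing any model variable are dropped
    and the count of samples actually used is recorded in ``n``.  Probes with
    zero variance across the used samples are dropped with a logged warning.
    """
    design, exposure_name = build_design(pheno, spec, surrogates)
    samples = design.index
    n = len(samples)
    if n < design.shape[1] + 2:
        raise ValueError("fewer complete-case samples than model parameters + 2")

    sub = meth[samples]
    variances = sub.to_numpy().var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = int((~keep).sum())
        logger.warning("dropping %d zero-variance probes", dropped)
        sub = sub.loc[keep]
    probe_ids = sub.index.to_numpy()

    X = design.to_numpy(dtype=float)
    p_cols = X.shape[1]
    df = n - p_cols

    if spec.orientation == "methylation_outcome":
        Y = sub.to_numpy(dtype=float).T  # samples x probes
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ X.T @ Y
        resid = Y - X @ B
        rss = np.einsum("ij,ij->j", resid, resid)
        j = design.columns.get_loc(exposure_name)
        sigma2 = rss / df
        se = np.sqrt(np.clip(sigma2 * XtX_inv[j, j], 0.0, None))
        effect = B[j]
        return _summary_frame(
            probe_ids, effect, se, df, spec, n, cohort, ancestry, ci_level, ci_method
        )

    # trait_outcome: outcome is the (transformed) trait, methylation enters
    # as the per-probe predictor of interest.
    y = design[exposure_name].to_numpy(dtype=float)
    X_cov = design.drop(columns=[exposure_name]).to_numpy(dtype=float)
    M = sub.to_numpy(dtype=float)
    m = M.shape[0]
    effect = np.empty(m)
    se = np.empty(m)
    df_t = n - (X_cov.shape[1] + 1)
    for i in range(m):
        Xi = np.column_stack([M[i], X_cov])
        XtX = Xi.T @ Xi
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular design for probe {probe_ids[i]!r}") from exc
        b = XtX_inv @ Xi.T @ y
        r = y - Xi @ b
        rss = float(r @ r)
        effect[i] = b[0]
        se[i] = np.sqrt(max(rss / df_t * XtX_inv[0, 0], 0.0))
    return _summary_frame(
        probe_ids, effect, se, df_t, spec, n, cohort, ancestry, ci_level, ci_method
    )


def genomewide_hits(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Rows with p below threshold, sorted by p then probe_id."""
    if table.empty:
        raise ValueError("summary table is empty")
    hits = table[table["p"] < threshold]
    return hits.sort_values(["p", "probe_id"], kind="mergesort").reset_index(drop=True)
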