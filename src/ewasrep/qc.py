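"""Detection p-value quality control for samples and probes.

A sample is excluded when the fraction of its probes with detection p above
the threshold exceeds the allowed failing fraction; a probe likewise over
samples.  Both failing fractions are evaluated on the full matrix before any
removal, so the exclusion sets are order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class QCReport:
    excluded_samples: list[str]
    excluded_probes: list[str]
    sample_fail_fraction: dict[str, float]
    probe_fail_fraction: dict[str, float]
    p_threshold: float = 0.01
    max_fail_fraction: float = 0.05

    def to_json(self) -> str:
        return json.dumps(
            {
                "excluded_samples": self.excluded_samples,
                "excluded_probes": self.excluded_probes,
                "sample_fail_fraction": self.sample_fail_fraction,
                "probe_fail_fraction": self.probe_fail_fraction,
                "p_threshold": self.p_threshold,
                "max_fail_fraction": self.max_fail_fraction,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "QCReport":
        return cls(**json.loads(text))


def qc_filter(
    det: pd.DataFrame,
    p_threshold: float = 0.01,
    max_fail_fraction: float = 0.05,
    iterative: bool = False,
) -> QCReport:
    """Classify samples and probes as excluded based on detection p-values.

    ``det`` is a probes x samples matrix of detection p-values.  Comparisons
    are strict: an entry fails when p > ``p_threshold``; an entity is excluded
    when its failing fraction is > ``max_fail_fraction``.  With
    ``iterative=True`` the two exclusion sets are re-evaluated on the reduced
    matrix until stable.
    """
    if det.size == 0:
        raise ValueError("detection matrix is empty")
    for name, value in (("p_threshold", p_threshold), ("max_fail_fraction", max_fail_fraction)):
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must lie strictly inside (0, 1); got {value}")

    failing = det.to_numpy() > p_threshold
    probe_frac = pd.Series(failing.mean(axis=1), index=det.index)
    sample_frac = pd.Series(failing.mean(axis=0), index=det.columns)

    bad_probes = probe_frac[probe_frac > max_fail_fraction]
    bad_samples = sample_frac[sample_frac > max_fail_fraction]

    if iterative:
        while True:
            sub = det.drop(index=bad_probes.index, columns=bad_samples.index)
            if sub.size == 0:
                break
            f = sub.to_numpy() > p_threshold
            pf = pd.Series(f.mean(axis=1), index=sub.index)
            sf = pd.Series(f.mean(axis=0), index=sub.columns)
            new_p = pf[pf > max_fail_fraction]
            new_s = sf[sf > max_fail_fraction]
            if new_p.empty and new_s.empty:
                break
            bad_probes = pd.concat([bad_probes, new_p])
            bad_samples = pd.concat([bad_samples, new_s])

    return QCReport(
        excluded_samples=list(bad_samples.index),
        excluded_probes=list(bad_probes.index),
        sample_fail_fraction={str(k): float(v) for k, v in bad_samples.items()},
        probe_fail_fraction={str(k): float(v) for k, v in bad_probes.items()},
        p_threshold=p_threshold,
        max_fail_fraction=max_fail_fraction,
    )


def apply_qc(meth: pd.DataFrame, report: QCReport) -> pd.DataFrame:
    """Drop the report's excluded probes and samples, preserving order."""
    missing = [p for p in report.excluded_probes if p not in meth.index]
    if missing:
        raise KeyError(f"excluded probe {missing[0]!r} not present in the methylation matrix")
    missing = [s for s in report.excluded_samples if s not in meth.columns]
    if missing:
        raise KeyError(f"excluded sample {missing[0]!r} not present in the methylation matrix")
    return meth.drop(index=report.excluded_probes, columns=report.excluded_samples)
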