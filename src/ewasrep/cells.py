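"""Reference-based leukocyte cell-fraction estimation.

Constrained projection in the Houseman style: per sample, nonnegative least
squares of observed beta values at cell-discriminating probes against the
reference mean profiles, followed by sum-to-one normalization.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

DEFAULT_CELL_TYPES = ("Bcell", "CD4T", "CD8T", "Gran", "Mono", "NK")


def make_cell_reference(
    n_probes_per_type: int = 10,
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
    seed: int = 7,
    high: float = 0.85,
    low: float = 0.10,
    jitter: float = 0.03,
) -> pd.DataFrame:
    """Build a small synthetic discriminating-probe reference.

    Each cell type gets ``n_probes_per_type`` marker probes that are highly
    methylated in that type and lowly methylated elsewhere, with a little
    per-entry jitter so columns are well separated but not degenerate.
    """
    if len(cell_types) < 2:
        raise ValueError("a cell reference needs at least 2 cell types")
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    m = n_probes_per_type * k
    profile = np.full((m, k), low)
    for j in range(k):
        profile[j * n_probes_per_type : (j + 1) * n_probes_per_type, j] = high
    profile = np.clip(profile + rng.uniform(-jitter, jitter, profile.shape), 0.0, 1.0)
    index = pd.Index(
        [
            f"ref_{ct}_{i:02d}"
            for j, ct in enumerate(cell_types)
            for i in range(n_probes_per_type)
        ],
        name="probe_id",
    )
    return pd.DataFrame(profile, index=index, columns=list(cell_types))


def default_cell_reference() -> pd.DataFrame:
    """The 60-probe x 6-cell-type reference shipped with the package."""
    with resources.files("ewasrep.data").joinpath("cell_reference.tsv").open() as fh:
        ref = pd.read_csv(fh, sep="\t", index_col="probe_id")
    return ref


def estimate_cell_fractions(meth: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions.

    Per sample, minimizes ``||ref @ f - beta||^2`` over ``f >= 0`` on the
    probes shared between ``meth`` and ``ref``, then normalizes ``f`` to sum
    to 1.  Output row/column order follows ``meth``'s samples and ``ref``'s
    cell types, and is invariant to probe and sample ordering of the inputs.
    """
    if ref.isna().any().any():
        raise ValueError("cell reference contains missing entries")
    if ref.shape[1] < 2:
        raise ValueError("cell reference must contain at least 2 cell types")
    shared = ref.index.intersection(meth.index).sort_values()
    if len(shared) == 0:
        raise ValueError("no probes shared between methylation matrix and cell reference")
    A = ref.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError(
            "cell reference is rank-deficient on the shared probe set; "
            "cell types are not distinguishable"
        )
    Y = meth.loc[shared].to_numpy(dtype=float)
    out = np.empty((meth.shape[1], ref.shape[1]))
    for j in range(meth.shape[1]):
        f, _ = nnls(A, Y[:, j])
        total = f.sum()
        out[j] = f / total if total > 0 else np.full(ref.shape[1], 1.0 / ref.shape[1])
    fractions = pd.DataFrame(out, index=meth.columns, columns=ref.columns)
    fractions.index.name = "sample_id"
    fractions.attrs["n_shared_probes"] = int(len(shared))
    return fractions
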