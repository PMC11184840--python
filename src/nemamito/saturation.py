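"""Entropy-based substitution-saturation testing.

A fully saturated alignment column is a multinomial draw from the pooled
base frequencies: past substitutions have erased all phylogenetic signal.
The index computed here is the mean per-column Shannon entropy of resolved
sites, normalized by the entropy of the pooled base frequencies (rather
than log2(4), which would overstate the ceiling in strongly AT-rich
genomes).  The observed index is compared against a Monte-Carlo
full-saturation null -- ``n_reps`` alignments of the same shape with every
column drawn iid from the pooled frequencies -- via a z-score and a
one-sided empirical p-value for falling below the null.

Verdict bands on z (configurable): ``not_saturated`` when z <= -6,
``saturated`` when z >= -2, ``substantial`` in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AlignmentBlock, SiteMask, build_site_mask

MIN_TAXA = 4
MIN_SITES = 20

VERDICT_NOT = "not_saturated"
VERDICT_SUBSTANTIAL = "substantial"
VERDICT_SATURATED = "saturated"

_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


def site_entropy(column: str) -> float:
    """Shannon entropy (bits) of one resolved alignment column."""
    if not column:
        raise ValueError("empty column")
    idx = _BASE_TO_IDX[np.frombuffer(column.upper().encode(), dtype=np.uint8)]
    if (idx == 255).any():
        raise ValueError(f"column {column!r} contains unresolved characters")
    counts = np.bincount(idx, minlength=4)
    p = counts[counts > 0] / len(column)
    return float(-(p * np.log2(p)).sum())


def _column_entropies(matrix: np.ndarray) -> np.ndarray:
    """Entropy of each column of an (n_taxa, n_sites) base-index matrix."""
    n = matrix.shape[0]
    counts = np.stack([(matrix == b).sum(axis=0) for b in range(4)])
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=0)


def _pooled_entropy(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    freqs = np.bincount(matrix.ravel(), minlength=4) / matrix.size
    nz = freqs[freqs > 0]
    return freqs, float(-(nz * np.log2(nz)).sum())


def iss(matrix: np.ndarray) -> float:
    """Entropy-based saturation index of a resolved-site base-index matrix.

    ``matrix`` holds base indices 0..3, shape (n_taxa, n_sites).  Requires
    at least 4 taxa and 20 sites.  0 for an invariant alignment; near 1
    (up to finite-sample bias) at full saturation.
    """
    n_taxa, n_sites = matrix.shape
    if n_taxa < MIN_TAXA:
        raise ValueError(f"need >= {MIN_TAXA} taxa, got {n_taxa}")
    if n_sites < MIN_SITES:
        raise ValueError(f"need >= {MIN_SITES} resolved sites, got {n_sites}")
    _, h_max = _pooled_entropy(matrix)
    if h_max == 0.0:
        return 0.0  # single-base alignment: invariant by definition
    return float(_column_entropies(matrix).mean() / h_max)


def alignment_matrix(
    block: AlignmentBlock,
    taxa: list[str],
    codon_position: int | str = "all",
    mask: SiteMask | None = None,
) -> np.ndarray:
    """Resolved-site base-index matrix for a taxa subset at one codon position."""
    mask = mask or build_site_mask(block, taxa)
    keep = mask.resolved.copy()
    if codon_position != "all":
        keep &= block.codon_position_of_column == int(codon_position)
    cols = np.flatnonzero(keep)
    rows = [
        _BASE_TO_IDX[np.frombuffer(block.row(t).encode(), dtype=np.uint8)][cols]
        for t in taxa
    ]
    return np.asarray(rows, dtype=np.uint8)


@dataclass(frozen=True)
class SaturationResult:
    gene: str
    codon_position: str          # "1" / "2" / "3" / "all"
    clade: str
    n_taxa: int
    n_resolved_sites: int
    iss_obs: float
    null_mean: float
    null_sd: float
    z: float
    p_one_sided: float
    verdict: str
    n_reps: int
    seed: int


def saturation_test(
    block: AlignmentBlock,
    codon_position: int | str,
    clade_taxa: list[str],
    n_reps: int = 500,
    seed: int = 0,
    clade: str = "all",
    z_not_saturated: float = -6.0,
    z_saturated: float = -2.0,
) -> SaturationResult:
    """Test one gene x codon-position x clade slice against the saturation null.

    The null distribution is the index of ``n_reps`` same-shape alignments
    with columns drawn iid multinomial from the pooled base frequencies of
    the observed resolved sites.  ``p_one_sided`` is the empirical
    probability (add-one smoothed) of a null index at or below the observed
    one; small p means the data are far less saturated than the null.
    """
    if n_reps < 200:
        raise ValueError("n_reps must be >= 200 for a usable null")
    matrix = alignment_matrix(block, clade_taxa, codon_position)
    obs = iss(matrix)
    freqs, _ = _pooled_entropy(matrix)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(freqs)
    cum[-1] = 1.0
    n_taxa, n_sites = matrix.shape
    null = np.empty(n_reps)
    for r in range(n_reps):
        sim = np.searchsorted(cum, rng.random((n_taxa, n_sites))).astype(np.uint8)
        null[r] = iss(sim)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (obs - null_mean) / null_sd if null_sd > 0 else 0.0
    p = float((1 + (null <= obs).sum()) / (n_reps + 1))
    if z <= z_not_saturated:
        verdict = VERDICT_NOT
    elif z >= z_saturated:
        verdict = VERDICT_SATURATED
    else:
        verdict = VERDICT_SUBSTANTIAL
    return SaturationResult(
        gene=block.gene,
        codon_position=str(codon_position),
        clade=clade,
        n_taxa=n_taxa,
        n_resolved_sites=n_sites,
        iss_obs=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_one_sided=p,
        verdict=verdict,
        n_reps=n_reps,
        seed=seed,
    )
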