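"""Shared fixtures: genetic code, synthetic datasets, independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from nemamito.gencode import genetic_code
from nemamito.simulate import SyntheticConfig, build_dataset


@pytest.fixture(scope="session")
def code():
    return genetic_code(5)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """A small synthetic dataset (10 species, wrap enabled) plus ground truth."""
    outdir = tmp_path_factory.mktemp("synthetic")
    cfg = SyntheticConfig(seed=42, n_species=10, wrap_last_gene=True)
    truth = build_dataset(cfg, outdir)
    return outdir, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240618)


# ---------------------------------------------------------------------------
# independent oracles (deliberately written from first principles, not via the
# package's own counting code paths)

def oracle_sites(codon: str, code) -> tuple[float, float]:
    """Per-position synonymous-site fractions by direct neighbor enumeration."""
    s = 0.0
    aa = code.codon_to_aa[codon]
    for pos in range(3):
        syn = valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in code.stop_codons:
                continue
            valid += 1
            if code.codon_to_aa[mutant] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def oracle_differences(a: str, b: str, code) -> tuple[float, float]:
    """Path-averaged difference counts by explicit recursive path expansion."""

    def paths(cur, remaining):
        if not remaining:
            return [[]]
        out = []
        for pos in remaining:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            for tail in paths(nxt, [p for p in remaining if p != pos]):
                out.append([(cur, nxt)] + tail)
        return out

    diff = [i for i in range(3) if a[i] != b[i]]
    all_paths = paths(a, diff)
    legal = [
        p for p in all_paths
        if all(step[1] not in code.stop_codons for step in p)
    ]
    if not legal:
        legal = all_paths
    sds, nds = [], []
    for p in legal:
        sd = nd = 0
        for x, y in p:
            if (x not in code.stop_codons and y not in code.stop_codons
                    and code.codon_to_aa[x] == code.codon_to_aa[y]):
                sd += 1
            else:
                nd += 1
        sds.append(sd)
        nds.append(nd)
    return sum(sds) / len(sds), sum(nds) / len(nds)
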