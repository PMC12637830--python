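"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import io

import numpy as np
import pytest
from skbio import TreeNode

from agpopgen.core_io import VariantDataset
from agpopgen import synthetic_data as sd


def make_dataset(
    genotypes,
    positions=None,
    contig="3L",
    haplotypes=None,
    ref=None,
    alt=None,
    sample_ids=None,
) -> VariantDataset:
    """Build a VariantDataset from a plain genotype list/array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    return VariantDataset(
        contig=contig,
        positions=np.arange(1, m + 1) * 100 if positions is None else positions,
        ref=np.array(["A"] * m) if ref is None else np.asarray(ref),
        alt=np.array(["T"] * m) if alt is None else np.asarray(alt),
        genotypes=g,
        sample_ids=[f"s{i}" for i in range(n)] if sample_ids is None else sample_ids,
        haplotypes=haplotypes,
    )


def random_additive_tree(n_leaves: int, rng: np.random.Generator) -> TreeNode:
    """A random unrooted binary tree with branch lengths in U(0.1, 1);
    its tip-tip distances are additive by construction."""
    sub = {f"L{i}": f"L{i}" for i in range(n_leaves)}
    active = list(sub)
    while len(active) > 3:
        a, b = sorted(rng.choice(len(active), 2, replace=False), reverse=True)
        na, nb = active.pop(int(a)), active.pop(int(b))
        la, lb = rng.uniform(0.1, 1.0, 2)
        key = f"I{len(sub)}"
        sub[key] = f"({sub[na]}:{la:.4f},{sub[nb]}:{lb:.4f})"
        active.append(key)
    ls = rng.uniform(0.1, 1.0, 3)
    nwk = (
        f"({sub[active[0]]}:{ls[0]:.4f},{sub[active[1]]}:{ls[1]:.4f},"
        f"{sub[active[2]]}:{ls[2]:.4f});"
    )
    return TreeNode.read(io.StringIO(nwk))


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared by read-only tests."""
    cfg = sd.SimulationConfig(
        seed=1,
        samples_per_deme=30,
        n_variants=4000,
        sweep=sd.SweepSpec(start_snp=2000, end_snp=3499),
    )
    return sd.simulate_study(cfg)


@pytest.fixture(scope="session")
def bundle_dir(small_study, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    sd.write_fixture_bundle(small_study, d)
    return d
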