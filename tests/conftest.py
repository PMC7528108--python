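import numpy as np
import pandas as pd
import pytest

from qtlkit import SimConfig, syndata
from qtlkit.expr_prep import FeatureMatrix
from qtlkit.ld import DosageMatrix


@pytest.fixture(scope="session")
def small_sim():
    """A small cohort with planted eQTLs, annotations and GWAS leads."""
    cfg = SimConfig(n_samples=150, n_genes=12, eqtl_fraction=0.5, seed=7)
    return syndata.simulate_all(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """A cohort with no planted effects (eqtl_fraction = 0)."""
    cfg = SimConfig(n_samples=120, n_genes=10, eqtl_fraction=0.0, seed=11)
    return syndata.simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_dosages(dos, pos=None, chrom=None, ids=None, ref=None, alt=None):
    """Hand-built DosageMatrix for toy fixtures."""
    dos = np.asarray(dos, float)
    v = dos.shape[0]
    return DosageMatrix(
        dosages=dos,
        variant_ids=ids or [f"v{i}" for i in range(v)],
        chrom=np.asarray(chrom if chrom is not None else ["chr1"] * v, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, v + 1) * 1000),
        ref=ref or ["A"] * v,
        alt=alt or ["G"] * v,
        sample_ids=[f"S{i}" for i in range(dos.shape[1])],
    )


def make_features(values, gene_ids=None, tss=0, chrom="chr1", strand="+"):
    """Hand-built FeatureMatrix; values is features x samples array-like."""
    values = np.asarray(values, float)
    f, n = values.shape
    fids = [f"f{i}" for i in range(f)]
    genes = gene_ids or ["geneA"] * f
    annot = pd.DataFrame(
        {
            "feature_id": fids,
            "gene_id": genes,
            "chrom": chrom,
            "start": np.arange(f) * 100,
            "end": np.arange(f) * 100 + 50,
            "tss": tss,
            "strand": strand,
        }
    )
    vals = pd.DataFrame(values, index=fids, columns=[f"S{i}" for i in range(n)])
    return FeatureMatrix(values=vals, annot=annot)
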