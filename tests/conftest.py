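import pytest

from clonalvar import synth


@pytest.fixture(scope="session")
def toy_genome():
    """A small annotated genome shared by mapping/calling tests."""
    return synth.generate_genome(length=20_000, gc_fraction=0.35, n_genes=8,
                                 mean_gene_length=600, seed=42)


@pytest.fixture(scope="session")
def recovery_result():
    """One full parameter-recovery run under the study conditions
    (100 kb, 30 genes, 15 SNPs + 2 short indels + 8 kb duplication +
    759 bp deletion, 120x, 0.5% error, WTS self-calibration)."""
    from clonalvar.study import run_recovery_study

    return run_recovery_study(seed=1)
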