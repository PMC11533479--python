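import numpy as np
import pytest

from mrmediate import (
    HarmonizedSet,
    SimulationConfig,
    SummaryStatSet,
    VariantAssociation,
    simulate_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_record(snp_id="rs1", beta=0.1, se=0.02, pval=1e-9, eaf=0.3, n=10_000,
                effect_allele="A", other_allele="G"):
    return VariantAssociation(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def random_sumstats(rng, n=50, trait_id="trait", trait_type="quantitative"):
    """A syntactically valid random summary-stat set (no causal structure)."""
    alleles = np.array(list("ACGT"))
    records = []
    for i in range(n):
        ea, oa = rng.choice(4, size=2, replace=False)
        records.append(
            VariantAssociation(
                snp_id=f"rs{i + 1}",
                effect_allele=alleles[ea],
                other_allele=alleles[oa],
                eaf=float(rng.uniform(0.01, 0.99)),
                beta=float(rng.normal(0, 0.1)),
                se=float(rng.uniform(0.005, 0.05)),
                pval=float(rng.uniform(1e-12, 1.0)),
                n=int(rng.integers(1_000, 500_000)),
            )
        )
    return SummaryStatSet(trait_id, trait_type, records)


def make_harmonized(bx, sx, by, sy, outcome_type="binary"):
    ids = [f"rs{i + 1}" for i in range(len(bx))]
    return HarmonizedSet(
        snp_ids=ids,
        beta_exp=np.asarray(bx, dtype=float),
        se_exp=np.asarray(sx, dtype=float),
        beta_out=np.asarray(by, dtype=float),
        se_out=np.asarray(sy, dtype=float),
        actions={s: "kept" for s in ids},
        outcome_type=outcome_type,
    )


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across tests (single mediator)."""
    cfg = SimulationConfig(
        n_snps=40,
        n_mediator_snps=20,
        n_per_cohort=(25_000, 25_000, 25_000),
        n_ld=8_000,
        delta_sd=0.12,
        seed=11,
    )
    return simulate_study(cfg)
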