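import pytest

import dnmkit as dk


@pytest.fixture(scope="session")
def lb_preset():
    return dk.load_preset("LB")


@pytest.fixture(scope="session")
def sim_moderate():
    """A 100 kb trio with an elevated mutation rate and somatic events, so
    every pipeline stage has work to do."""
    config = dk.SimulationConfig(
        genome_length=100_000, mu_true=2e-4, n_somatic=10,
        somatic_cell_fraction=(0.1, 0.25),
    )
    return dk.simulate_trio(config, 11)


@pytest.fixture
def trio():
    return dk.Trio("F", "M", "C")


def make_call(gt=None, dp=None, ad=None, gq=None, pl=None, **kw):
    return dk.SampleCall(gt=gt, dp=dp, ad=ad, gq=gq, pl=pl, **kw)


def make_record(
    f=(0, 0), m=(0, 0), c=(0, 1),
    pos=100, ref="A", alts=("G",),
    dp=30, gq=99,
    annotations=None,
    **call_kwargs,
):
    """Hand-built biallelic trio record with comfortable default qualities."""
    def call(gt):
        if gt is None:
            return dk.SampleCall()
        n_alt = {0: 0, 1: dp // 2, 2: dp}[sum(gt)]
        return dk.SampleCall(
            gt=gt, dp=dp, ad=(dp - n_alt, n_alt), gq=gq,
            pl=(0, 300, 600) if gt == (0, 0) else ((300, 0, 300) if sum(gt) == 1 else (600, 300, 0)),
            **call_kwargs,
        )

    return dk.TrioSiteRecord(
        chrom="chr1", pos=pos, ref_allele=ref, alt_alleles=tuple(alts),
        annotations=annotations or dk.SiteAnnotations(),
        calls={"F": call(f), "M": call(m), "C": call(c)},
    )


@pytest.fixture
def permissive_config():
    """A config with every filter disabled (homref violation mode only)."""
    return dk.FilterConfig(name="permissive")
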