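import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neoepi.synthetic import FixtureConfig, generate_cohort
from neoepi.variant_io import AnnotatedVariant

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def make_variant(
    variant_id: str = "v1",
    protein: str = "M" + "A" * 20,
    protein_pos: int = 11,
    mt: str = "W",
    gene: str = "GENE1",
    **kw,
) -> AnnotatedVariant:
    defaults = dict(
        chrom="chr1",
        pos=1000,
        ref_base="C",
        alt_base="T",
        transcript_id="TX1",
    )
    defaults.update(kw)
    return AnnotatedVariant(
        variant_id=variant_id,
        gene=gene,
        wt_residue=protein[protein_pos - 1],
        protein_pos=protein_pos,
        mt_residue=mt,
        wt_protein_seq=protein,
        **defaults,
    )


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """A 200-variant synthetic cohort shared across end-to-end tests."""
    outdir = tmp_path_factory.mktemp("cohort")
    config = FixtureConfig(seed=11)
    return config, generate_cohort(config, outdir)
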