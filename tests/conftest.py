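import pytest

from cleavemap import DisplayContext, motif_model


@pytest.fixture
def context():
    return DisplayContext()


@pytest.fixture
def chymase_model():
    """Planted chymase-like truth: P1 uniform on F/Y/W, P2' acidic mass 0.5."""
    return motif_model("FYW", p2prime_acidic_mass=0.5)


@pytest.fixture
def elastase_model():
    """Planted elastase-like truth: P1 uniform on V/A/I."""
    return motif_model("VAI")


def make_single_site_model(p_site: float, p1_residues: str = "F"):
    """Model whose every admissible site has cleavage probability exactly p_site.

    All non-P1 subsites are uniform (weight 1/20) and the P1 weight is spread
    uniformly over ``p1_residues``, so the weight product is identical for
    every admissible site (arm and out-of-construct positions contribute the
    same 1/20 factor); motif_model's saturation then IS the per-site
    probability.
    """
    return motif_model(p1_residues, saturation=p_site)
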