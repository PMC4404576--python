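import pytest

import mbison as mb


@pytest.fixture
def toy_background():
    """Hand-built 8-gene / 3-family background with known structure."""
    pairs = (
        [("miR-A", g) for g in (1, 2, 3, 4, 5)]
        + [("miR-B", g) for g in (1, 2)]
        + [("miR-C", g) for g in (3, 6, 7, 8)]
    )
    return mb.Background.from_pairs(pairs)


@pytest.fixture(scope="session")
def study_background():
    """Session-wide 200-gene / 20-family synthetic background, unbiased."""
    spec = mb.FixtureSpec(200, 20, 0.3, 0.5, 1.0, seed=42)
    return mb.synthetic_background(spec)


@pytest.fixture(scope="session")
def biased_study():
    """bias_factor=2 background plus its long-UTR gene group."""
    from mbison.synthdata import _plan_background

    spec = mb.FixtureSpec(200, 20, 0.3, 0.5, 2.0, seed=42)
    plan = _plan_background(spec)
    bgr = mb.Background.from_pairs(plan["pairs"])
    long_genes = [g for g in plan["long_genes"] if g in bgr.gene_universe]
    return bgr, long_genes


@pytest.fixture(scope="session")
def background_dir(tmp_path_factory):
    """On-disk prediction + idmap tables for a 40-gene / 6-family fixture."""
    outdir = tmp_path_factory.mktemp("bgtables")
    spec = mb.FixtureSpec(40, 6, 0.3, 0.5, 1.0, seed=7)
    pred, idmap, manifest = mb.generate_background_table(spec, outdir)
    return {"dir": outdir, "pred": pred, "idmap": idmap, "manifest": manifest, "spec": spec}
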