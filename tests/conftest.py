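import pytest

from zoomkey.builder import BuildConfig, build
from zoomkey.fixtures import FixtureSpec, gen_images, gen_matrix_csv

TOY_CSV = """Taxon,Achene cross-section shape
Carex alpha,trigonous
Carex beta,lenticular
Carex gamma,trigonous|lenticular
"""


@pytest.fixture
def toy_csv():
    return TOY_CSV


@pytest.fixture(scope="session")
def standard_fixture(tmp_path_factory):
    """The standard study set: 12 taxa, 30 images, built once per session.

    PNG tiles so pixel-exact checks are possible downstream.
    """
    root = tmp_path_factory.mktemp("standard")
    spec = FixtureSpec(
        n_taxa=12,
        images_per_taxon=3,  # 36 generated; manifest trimmed to 30 below
        image_dims=((512, 384), (384, 512), (400, 300)),
        unknown_rate=0.2,
        seed=7,
    )
    (root / "matrix.csv").write_text(gen_matrix_csv(spec))
    entries = gen_images(spec, root / "images")
    # keep 30 images: drop the last photo of the final 6 taxa
    from zoomkey.collection import write_manifest

    keep = [e for e in entries if not (e.file.endswith("photo2.png")
                                       and int(e.taxon.split()[-1]) > 6)]
    assert len(keep) == 30
    (root / "images" / "manifest.csv").write_text(write_manifest(keep))
    config = BuildConfig(
        matrix_path=root / "matrix.csv",
        manifest_path=root / "images" / "manifest.csv",
        images_dir=root / "images",
        out_dir=root / "out",
        format="png",
    )
    report = build(config)
    return {"root": root, "config": config, "report": report, "spec": spec}
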