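import warnings

import pytest

from chromae.annotation import read_annotation
from chromae.coverage import open_track
from chromae.enrichment import build_enrichment_table
from chromae.simulate import SyntheticConfig, generate_dataset
from chromae.training import join_features_labels, read_labels

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(n_genes=120, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_cfg, tmp_path_factory):
    """120-gene synthetic input bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = generate_dataset(small_cfg, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def small_table(small_bundle):
    """Enrichment table built from the small bundle (chrX decoys excluded)."""
    outdir, truth = small_bundle
    genes = read_annotation(outdir / "genes.bed", "bed")
    autosomal = [g for g in genes if g.chrom != "chrX"]
    tracks = {
        "H3K36me3": open_track(outdir / "H3K36me3.bedgraph"),
        "H3K27me3": open_track(outdir / "H3K27me3.bedgraph"),
    }
    control = open_track(outdir / "control.bedgraph")
    table, _ = build_enrichment_table(tracks, control, autosomal)
    return table


@pytest.fixture(scope="session")
def study_cfg():
    """Study-scale generating conditions: 500 genes, 10% MAE prevalence,
    class separation of 4 within-class SDs."""
    return SyntheticConfig(n_genes=500, mae_fraction=0.10, separation=4.0,
                           seed=11)


@pytest.fixture(scope="session")
def study_bundle(study_cfg, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("study")
    truth = generate_dataset(study_cfg, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def study_design(study_bundle):
    outdir, truth = study_bundle
    genes = read_annotation(outdir / "genes.bed", "bed")
    autosomal = [g for g in genes if g.chrom != "chrX"]
    tracks = {
        "H3K36me3": open_track(outdir / "H3K36me3.bedgraph"),
        "H3K27me3": open_track(outdir / "H3K27me3.bedgraph"),
    }
    control = open_track(outdir / "control.bedgraph")
    table, _ = build_enrichment_table(tracks, control, autosomal)
    labels = read_labels(outdir / "labels.tsv")
    return join_features_labels(table, labels)


@pytest.fixture(scope="session")
def small_design(small_bundle, small_table):
    outdir, truth = small_bundle
    labels = read_labels(outdir / "labels.tsv")
    return join_features_labels(small_table, labels)
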