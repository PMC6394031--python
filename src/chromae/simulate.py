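"""Synthetic inputs with the statistical structure the classifier assumes.

Genes are placed non-overlapping on one synthetic autosome ("chrS", plus a
small "chrX" decoy to exercise the X-exclusion filter). Per-gene target
mean signals for H3K36me3 and H3K27me3 are drawn from two bivariate
log-normal clusters: BAE genes are high-H3K36me3 / low-H3K27me3 (active,
not silenced), while the minority MAE class is elevated in both marks —
the joint gene-body signature of monoallelic expression in polyclonal
samples. Coverage tracks are written as per-bin signal (constant target
plus seeded multiplicative noise) in bedGraph text, so the whole bundle
round-trips through the pipeline's own readers with no binary formats.

The exact marginal shape is irrelevant downstream — quantile ranking
destroys scale — only the cluster geometry in rank space matters, which is
precisely why the rank transform makes the features portable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .evaluation import BAE, MAE

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "bayes_oracle"]

#: within-class standard deviation of log target signal, both marks
SIGNAL_LOG_SD = 1.0
#: BAE cluster mean in log-signal space: (log H3K36me3, log H3K27me3)
BAE_LOG_MEAN = (1.0, 0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters.

    ``mae_fraction`` defaults to 0.10, inside the 5-20% prevalence range
    of MAE genes among expressed genes, so training sets are naturally
    imbalanced. ``separation`` is the Euclidean distance between the class
    means in log-signal space, in within-class-SD units; 4 gives nearly
    separable classes, 0 makes them indistinguishable. ``noise_sd`` is the
    SD of the per-bin multiplicative log-normal track noise.
    """

    n_genes: int = 500
    mae_fraction: float = 0.10
    separation: float = 4.0
    gene_length_range: tuple[int, int] = (1000, 5000)
    noise_sd: float = 0.25
    seed: int = 0
    n_x_genes: int = 5
    bin_size: int = 50

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not 0 <= self.mae_fraction <= 1:
            raise ValueError("mae_fraction must be in [0, 1]")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must satisfy 0 < min <= max")

    @property
    def class_means(self) -> tuple[np.ndarray, np.ndarray]:
        """(BAE, MAE) cluster means in log-signal space."""
        bae = np.array(BAE_LOG_MEAN)
        shift = self.separation * SIGNAL_LOG_SD / np.sqrt(2.0)
        return bae, bae + shift


@dataclass
class SyntheticTruth:
    """Realized labels plus the generating parameters and latent classes."""

    labels: dict[str, str]
    latent_class: dict[str, int]  # 1 = MAE, 0 = BAE
    config: SyntheticConfig

    @property
    def n_mae(self) -> int:
        return sum(self.latent_class.values())


def _place_genes(rng, chrom, n, length_range, start=1000):
    """Non-overlapping gene intervals with random gaps along one chromosome."""
    lo, hi = length_range
    pos = start
    intervals = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        intervals.append((chrom, pos, pos + length))
        pos += length + int(rng.integers(200, 1001))
    return intervals


def _write_bedgraph(path, rows):
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")


def generate_dataset(cfg: SyntheticConfig, outdir: str | Path) -> SyntheticTruth:
    """Write the full synthetic input bundle into *outdir*.

    Produces genes.bed, H3K36me3.bedgraph, H3K27me3.bedgraph,
    control.bedgraph, labels.tsv, expression.tsv and manifest.json; the
    run is fully determined by the config (identical configs give
    byte-identical files). Labels cover the autosomal genes only — truth
    calls from clonal lines are autosomal — while the chrX decoy genes
    carry BAE-like signal and no label.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    autosomal = _place_genes(rng, "chrS", cfg.n_genes, cfg.gene_length_range)
    decoys = _place_genes(rng, "chrX", cfg.n_x_genes, cfg.gene_length_range)

    latent = rng.random(cfg.n_genes) < cfg.mae_fraction
    bae_mean, mae_mean = cfg.class_means

    gene_ids = [f"gene_{i + 1:05d}" for i in range(cfg.n_genes)]
    decoy_ids = [f"xgene_{i + 1:03d}" for i in range(cfg.n_x_genes)]

    # per-gene target mean signals (log-normal clusters)
    log_targets = np.empty((cfg.n_genes + cfg.n_x_genes, 2))
    for i in range(cfg.n_genes):
        mean = mae_mean if latent[i] else bae_mean
        log_targets[i] = rng.normal(mean, SIGNAL_LOG_SD)
    for j in range(cfg.n_x_genes):
        log_targets[cfg.n_genes + j] = rng.normal(bae_mean, SIGNAL_LOG_SD)
    targets = np.exp(log_targets)  # columns: H3K36me3, H3K27me3
    controls = rng.uniform(0.8, 1.2, size=cfg.n_genes + cfg.n_x_genes)

    all_ids = gene_ids + decoy_ids
    all_intervals = autosomal + decoys

    # annotation (BED6, alternating strands)
    with open(outdir / "genes.bed", "w") as fh:
        for i, (gid, (chrom, start, end)) in enumerate(
            zip(all_ids, all_intervals)
        ):
            strand = "+" if i % 2 == 0 else "-"
            fh.write(f"{chrom}\t{start}\t{end}\t{gid}\t0\t{strand}\n")

    # coverage tracks: per-bin target with multiplicative log-normal noise
    mark_rows: dict[str, list] = {"H3K36me3": [], "H3K27me3": []}
    control_rows = []
    for i, (chrom, start, end) in enumerate(all_intervals):
        edges = list(range(start, end, cfg.bin_size)) + [end]
        n_bins = len(edges) - 1
        for m, mark in enumerate(("H3K36me3", "H3K27me3")):
            noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=n_bins))
            for b in range(n_bins):
                mark_rows[mark].append(
                    (chrom, edges[b], edges[b + 1], targets[i, m] * noise[b])
                )
        control_rows.append((chrom, start, end, controls[i]))

    _write_bedgraph(outdir / "H3K36me3.bedgraph", mark_rows["H3K36me3"])
    _write_bedgraph(outdir / "H3K27me3.bedgraph", mark_rows["H3K27me3"])
    _write_bedgraph(outdir / "control.bedgraph", control_rows)

    labels = {gid: (MAE if latent[i] else BAE)
              for i, gid in enumerate(gene_ids)}
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("gene_id\tstatus\n")
        for gid in gene_ids:
            fh.write(f"{gid}\t{labels[gid]}\n")

    # expression values (arbitrary positive units) for the expression filter
    expression = np.exp(rng.normal(2.0, 1.0, size=len(all_ids)))
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gid, v in zip(all_ids, expression):
            fh.write(f"{gid}\t{v:.4f}\n")

    manifest = asdict(cfg)
    manifest["gene_length_range"] = list(cfg.gene_length_range)
    manifest["n_mae_realized"] = int(latent.sum())
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return SyntheticTruth(
        labels=labels,
        latent_class={gid: int(latent[i]) for i, gid in enumerate(gene_ids)},
        config=cfg,
    )


def bayes_oracle(
    cfg: SyntheticConfig, n_draws: int = 1_000_000, seed: int | None = None
) -> tuple[float, float]:
    """Optimal-classifier accuracy and kappa for the generating mixture.

    Estimated by seeded Monte Carlo on the latent log-signal mixture: draw
    class and signal, classify by maximum posterior under the known
    equal-covariance Gaussian densities, and score against the latent
    class. Quantile ranking is monotone per coordinate, so this ceiling
    also bounds any classifier operating in rank space.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    f = cfg.mae_fraction
    bae_mean, mae_mean = cfg.class_means

    z = rng.random(n_draws) < f
    means = np.where(z[:, None], mae_mean, bae_mean)
    x = rng.normal(means, SIGNAL_LOG_SD)

    # log-posterior ratio for equal isotropic covariance
    d_mae = np.sum((x - mae_mean) ** 2, axis=1)
    d_bae = np.sum((x - bae_mean) ** 2, axis=1)
    with np.errstate(divide="ignore"):
        log_prior = np.log(f) - np.log1p(-f) if 0 < f < 1 else (
            np.inf if f == 1 else -np.inf
        )
    score = (d_bae - d_mae) / (2 * SIGNAL_LOG_SD**2) + log_prior
    call_mae = score > 0

    accuracy = float(np.mean(call_mae == z))
    # kappa from the Monte-Carlo confusion counts
    tp = float(np.sum(call_mae & z))
    fp = float(np.sum(call_mae & ~z))
    fn = float(np.sum(~call_mae & z))
    tn = float(np.sum(~call_mae & ~z))
    n = tp + fp + fn + tn
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = 0.0 if p_e == 1 else (p_o - p_e) / (1 - p_e)
    return accuracy, kappa
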