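"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a dose-response perturbation design: three
exchangeable ethanol-control groups (required by the control-calibrated FDR
estimator), one signal at three dose levels, three biological replicates
per condition. Genes sit on a virtual genome with peaks placed within
+/-50 kb of each TSS so the nearest-TSS rule maps them back to their gene.
ATAC fragment counts are negative binomial (variance mu + alpha*mu^2);
expression is log-normal TPM around a per-gene baseline. Ground-truth
labels (truly differential peaks, truly DE genes, concordance class) are
emitted for parameter-recovery tests.

Key structural knobs mirror the observed data: ``frac_concordant`` sets the
fraction of DE genes carrying at least one truly differential peak in their
expression direction, and ``baseline_shift_nonconcordant`` elevates the
baseline accessibility of peaks near nonconcordant DE genes — the regime
in which strong expression changes occur over already-open chromatin.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import io as pio
from .types import CountMatrix, GeneModel, GenomicInterval, SampleInfo

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "simulate_peak_counts",
    "jittered_summit_replicates",
    "write_fixture_bundle",
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 500
    peaks_per_gene_distribution: tuple[str, dict] = ("poisson", {"lam": 4.0})
    n_control_groups: int = 3
    replicates_per_condition: int = 3
    dose_levels: int = 3
    baseline_mean: float = 100.0
    nb_dispersion: float = 0.1
    depth_factors: Sequence[float] | None = None
    frac_de_genes: float = 0.2
    frac_concordant: float = 0.5
    accessibility_effect: float = 4.0
    expression_effect: float = 2.0  # log2FC magnitude at the top dose
    baseline_shift_nonconcordant: float = 2.0
    motif_set: list[tuple[str, str]] = field(default_factory=list)
    # geometry of the virtual genome
    peak_width: int = 200
    peak_window: int = 50_000
    gene_spacing: int = 200_000
    gene_body_length: int = 20_000
    n_chromosomes: int = 1
    # expression model
    expression_baseline_log_mean: float = np.log(20.0)
    expression_baseline_log_sd: float = 1.0
    expression_noise_sd: float = 0.25  # log2-scale per-sample noise
    frac_diff_peaks_per_concordant_gene: float = 0.5
    sequence_length: int = 200

    def validate(self) -> None:
        for name in ("frac_de_genes", "frac_concordant",
                     "frac_diff_peaks_per_concordant_gene"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.accessibility_effect < 1:
            raise ValueError("accessibility_effect is a fold change >= 1")
        if self.expression_effect < 0:
            raise ValueError("expression_effect must be >= 0")
        if self.baseline_shift_nonconcordant < 1:
            raise ValueError("baseline_shift_nonconcordant must be >= 1")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        if self.n_control_groups < 1 or self.dose_levels < 1:
            raise ValueError("need >= 1 control group and >= 1 dose level")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")

    @property
    def control_conditions(self) -> list[str]:
        return [f"EtOH-{i + 1}" for i in range(self.n_control_groups)]

    @property
    def experimental_conditions(self) -> list[str]:
        return [f"dose-{i + 1}" for i in range(self.dose_levels)]


@dataclass
class SyntheticTruth:
    true_diff_peaks: dict[str, str]  # peak_id -> "up" | "down"
    true_de_genes: dict[str, tuple[str, float]]  # gene_id -> (direction, log2fc)
    gene_class: dict[str, str]  # gene_id -> concordant | nonconcordant | null
    motif_membership: dict[str, set[str]]

    def to_json_dict(self) -> dict:
        return {
            "true_diff_peaks": self.true_diff_peaks,
            "true_de_genes": {
                g: {"direction": d, "log2fc": fc}
                for g, (d, fc) in self.true_de_genes.items()
            },
            "gene_class": self.gene_class,
            "motif_membership": {
                m: sorted(peaks) for m, peaks in self.motif_membership.items()
            },
        }


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    peaks: list[GenomicInterval]
    atac: CountMatrix
    expression: CountMatrix
    truth: SyntheticTruth
    gene_peaks: dict[str, list[str]]
    peak_sequences: dict[str, str] = field(default_factory=dict)

    @property
    def control_conditions(self) -> list[str]:
        return self.config.control_conditions

    @property
    def experimental_conditions(self) -> list[str]:
        return self.config.experimental_conditions


def _nb_draw(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def _draw_peak_counts(rng: np.random.Generator, law: tuple[str, dict], n: int) -> np.ndarray:
    name, params = law
    if name == "poisson":
        return rng.poisson(params.get("lam", 4.0), size=n)
    if name == "fixed":
        return np.full(n, int(params["k"]))
    if name == "geometric":
        return rng.geometric(params["p"], size=n) - 1
    raise ValueError(f"unknown peaks-per-gene law {name!r}")


_MOTIF_SITES = {  # consensus sites planted into peak sequences
    "default": "TGACGTCAGG",
}


def _build_samples(config: SimulationConfig) -> list[SampleInfo]:
    samples = []
    for cond in config.control_conditions:
        for r in range(1, config.replicates_per_condition + 1):
            samples.append(SampleInfo(f"{cond}_r{r}", cond, r, "control"))
    for cond in config.experimental_conditions:
        for r in range(1, config.replicates_per_condition + 1):
            samples.append(SampleInfo(f"{cond}_r{r}", cond, r, "experimental"))
    return samples


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate genes, peaks, ATAC and expression matrices plus ground truth.

    Identical config (including seed) gives byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _build_samples(config)
    n_samples = len(samples)
    depth = (
        np.ones(n_samples)
        if config.depth_factors is None
        else np.asarray(config.depth_factors, dtype=float)
    )
    if depth.shape != (n_samples,):
        raise ValueError(f"depth_factors must have length {n_samples}")
    if np.any(depth <= 0):
        raise ValueError("depth_factors must be positive")

    # --- genes on a virtual genome, bodies non-overlapping ----------------
    genes = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    for i in range(config.n_genes):
        chrom = f"chrS{i // per_chrom + 1}"
        slot = i % per_chrom
        tss = 100_000 + slot * config.gene_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene_{i + 1:05d}",
                chrom=chrom,
                tss=tss,
                strand=strand,
                gene_start=tss,
                gene_end=tss + config.gene_body_length,
            )
        )

    # --- truth labels -----------------------------------------------------
    n_de = int(round(config.frac_de_genes * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    n_conc = int(round(config.frac_concordant * n_de))
    conc_set = set(de_idx[:n_conc])  # rng.choice order is already random
    de_set = set(de_idx)
    directions = {
        int(i): ("up" if rng.random() < 0.5 else "down") for i in sorted(de_set)
    }

    # --- peaks ------------------------------------------------------------
    k_per_gene = _draw_peak_counts(rng, config.peaks_per_gene_distribution,
                                   config.n_genes)
    k_per_gene = np.asarray(k_per_gene, dtype=int)
    for i in conc_set:
        k_per_gene[i] = max(1, k_per_gene[i])

    half_w = config.peak_width // 2
    raw_peaks: list[tuple[str, int, int, bool]] = []  # (chrom, mid, gene_idx, is_diff)
    for gi, g in enumerate(genes):
        k = k_per_gene[gi]
        if k == 0:
            continue
        offsets = rng.integers(-config.peak_window, config.peak_window + 1, size=k)
        diff_flags = np.zeros(k, dtype=bool)
        if gi in conc_set:
            diff_flags = rng.random(k) < config.frac_diff_peaks_per_concordant_gene
            if not diff_flags.any():
                diff_flags[rng.integers(k)] = True
        for off, is_diff in zip(offsets, diff_flags):
            raw_peaks.append((g.chrom, g.tss + int(off), gi, bool(is_diff)))

    raw_peaks.sort(key=lambda t: (t[0], t[1]))
    peaks: list[GenomicInterval] = []
    gene_peaks: dict[str, list[str]] = {g.gene_id: [] for g in genes}
    true_diff_peaks: dict[str, str] = {}
    peak_gene_idx = np.empty(len(raw_peaks), dtype=int)
    peak_is_diff = np.zeros(len(raw_peaks), dtype=bool)
    for pi, (chrom, mid, gi, is_diff) in enumerate(raw_peaks):
        pid = f"peak_{pi + 1:06d}"
        peaks.append(GenomicInterval(chrom, mid - half_w, mid + half_w, pid))
        gene_peaks[genes[gi].gene_id].append(pid)
        peak_gene_idx[pi] = gi
        peak_is_diff[pi] = is_diff
        if is_diff:
            true_diff_peaks[pid] = directions[gi]

    # --- ATAC counts ------------------------------------------------------
    n_peaks = len(peaks)
    dose_rank = np.array(
        [0.0] * (config.n_control_groups * config.replicates_per_condition)
        + [
            (d + 1) / config.dose_levels
            for d in range(config.dose_levels)
            for _ in range(config.replicates_per_condition)
        ]
    )
    base = np.full(n_peaks, config.baseline_mean)
    nonconc = np.array(
        [
            peak_gene_idx[pi] in de_set and peak_gene_idx[pi] not in conc_set
            for pi in range(n_peaks)
        ]
    )
    base[nonconc] *= config.baseline_shift_nonconcordant
    sign = np.zeros(n_peaks)
    for pi in range(n_peaks):
        if peak_is_diff[pi]:
            sign[pi] = 1.0 if directions[peak_gene_idx[pi]] == "up" else -1.0
    log_effect = np.log(config.accessibility_effect)
    mean_matrix = (
        base[:, None]
        * np.exp(sign[:, None] * dose_rank[None, :] * log_effect)
        * depth[None, :]
    )
    atac_values = _nb_draw(rng, mean_matrix, config.nb_dispersion)
    atac = CountMatrix([p.name for p in peaks], samples, atac_values, "fragments")

    # --- expression -------------------------------------------------------
    base_tpm = rng.lognormal(
        config.expression_baseline_log_mean,
        config.expression_baseline_log_sd,
        size=config.n_genes,
    )
    lfc = np.zeros(config.n_genes)
    true_de_genes: dict[str, tuple[str, float]] = {}
    gene_class: dict[str, str] = {}
    for gi, g in enumerate(genes):
        if gi in de_set:
            s = 1.0 if directions[gi] == "up" else -1.0
            lfc[gi] = s * config.expression_effect
            true_de_genes[g.gene_id] = (directions[gi], lfc[gi])
            gene_class[g.gene_id] = (
                "concordant" if gi in conc_set else "nonconcordant"
            )
        else:
            gene_class[g.gene_id] = "null"
    noise = rng.normal(0.0, config.expression_noise_sd,
                       size=(config.n_genes, n_samples))
    expr_values = (
        base_tpm[:, None]
        * 2.0 ** (lfc[:, None] * dose_rank[None, :])
        * 2.0**noise
    )
    expression = CountMatrix(
        [g.gene_id for g in genes], samples, expr_values, "TPM"
    )

    # --- peak sequences with planted motif sites --------------------------
    peak_sequences: dict[str, str] = {}
    motif_membership: dict[str, set[str]] = {}
    if config.motif_set:
        bases = np.array(list("ACGT"))
        seqs = [
            "".join(bases[rng.integers(0, 4, size=config.sequence_length)])
            for _ in range(n_peaks)
        ]
        for motif_id, rule in config.motif_set:
            site = _MOTIF_SITES.get(motif_id, _MOTIF_SITES["default"])
            if rule == "differential_up":
                target = [
                    pi for pi in range(n_peaks)
                    if peaks[pi].name in true_diff_peaks
                    and true_diff_peaks[peaks[pi].name] == "up"
                ]
            elif rule == "random":
                n_pick = max(1, n_peaks // 10)
                target = list(rng.choice(n_peaks, size=n_pick, replace=False))
            else:
                raise ValueError(f"unknown motif placement rule {rule!r}")
            members = set()
            for pi in target:
                pos = int(rng.integers(0, config.sequence_length - len(site) + 1))
                s = seqs[pi]
                seqs[pi] = s[:pos] + site + s[pos + len(site):]
                members.add(peaks[pi].name)
            motif_membership[motif_id] = members
        peak_sequences = {peaks[pi].name: seqs[pi] for pi in range(n_peaks)}

    truth = SyntheticTruth(true_diff_peaks, true_de_genes, gene_class,
                           motif_membership)
    return SyntheticDataset(config, genes, peaks, atac, expression, truth,
                            gene_peaks, peak_sequences)


def simulate_peak_counts(
    n_peaks: int,
    n_true: int,
    effect: float = 4.0,
    baseline_mean: float = 100.0,
    nb_dispersion: float = 0.1,
    n_control_groups: int = 3,
    n_experimental: int = 2,
    replicates: int = 3,
    depth_factors: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, set[str]]:
    """Peak-level null-plus-spike simulation for calibrating the FDR caller.

    All peaks are null in the control groups; ``n_true`` peaks carry a full
    ``effect``-fold increase in every experimental condition. Returns the
    raw count matrix and the set of truly differential peak ids.
    """
    if n_true > n_peaks:
        raise ValueError("n_true cannot exceed n_peaks")
    rng = np.random.default_rng(seed)
    samples = []
    for c in range(n_control_groups):
        for r in range(1, replicates + 1):
            samples.append(SampleInfo(f"EtOH-{c + 1}_r{r}", f"EtOH-{c + 1}", r,
                                      "control"))
    for e in range(n_experimental):
        for r in range(1, replicates + 1):
            samples.append(SampleInfo(f"exp-{e + 1}_r{r}", f"exp-{e + 1}", r,
                                      "experimental"))
    n_samples = len(samples)
    depth = (
        np.ones(n_samples)
        if depth_factors is None
        else np.asarray(depth_factors, dtype=float)
    )
    peak_ids = [f"peak_{i + 1:06d}" for i in range(n_peaks)]
    true_idx = rng.choice(n_peaks, size=n_true, replace=False)
    is_exp = np.array([s.role == "experimental" for s in samples])
    mean = np.full((n_peaks, n_samples), baseline_mean)
    mean[np.ix_(true_idx, is_exp)] *= effect
    mean *= depth[None, :]
    values = _nb_draw(rng, mean, nb_dispersion)
    return (
        CountMatrix(peak_ids, samples, values, "fragments"),
        {peak_ids[i] for i in true_idx},
    )


def jittered_summit_replicates(
    peaks: Sequence[GenomicInterval],
    n_replicates: int = 3,
    jitter: int = 10,
    dropout: float = 0.0,
    seed: int = 0,
) -> list[list[GenomicInterval]]:
    """Per-replicate summit calls: peak midpoints jittered by +/-jitter bp.

    ``dropout`` is the per-replicate probability a summit goes undetected,
    which gives the majority rule something to filter.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        rep = []
        for p in peaks:
            if dropout and rng.random() < dropout:
                continue
            pos = p.midpoint + int(rng.integers(-jitter, jitter + 1))
            rep.append(GenomicInterval(p.chrom, max(pos, 0), max(pos, 0) + 1))
        out.append(rep)
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(
    dataset: SyntheticDataset, out_dir: str, force: bool = False
) -> str:
    """Write the dataset as the plain-text bundle the parsers read back.

    Emits peaks.bed, genes.tsv, samples.tsv, atac_counts.tsv,
    expression.tsv, truth.json and manifest.json (with sha256 checksums).
    Refuses a non-empty existing directory unless ``force``.
    """
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    pio.ensure_dir(out_dir)
    paths = {
        "peaks.bed": os.path.join(out_dir, "peaks.bed"),
        "genes.tsv": os.path.join(out_dir, "genes.tsv"),
        "samples.tsv": os.path.join(out_dir, "samples.tsv"),
        "atac_counts.tsv": os.path.join(out_dir, "atac_counts.tsv"),
        "expression.tsv": os.path.join(out_dir, "expression.tsv"),
        "truth.json": os.path.join(out_dir, "truth.json"),
    }
    pio.write_interval_file(paths["peaks.bed"], dataset.peaks)
    pio.write_gene_table(paths["genes.tsv"], dataset.genes)
    pio.write_sample_sheet(paths["samples.tsv"], dataset.atac.samples)
    pio.write_count_matrix(paths["atac_counts.tsv"], dataset.atac)
    pio.write_count_matrix(paths["expression.tsv"], dataset.expression)
    with open(paths["truth.json"], "w") as fh:
        json.dump(dataset.truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest = {
        "seed": dataset.config.seed,
        "n_genes": dataset.config.n_genes,
        "files": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest_path
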