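"""Synthetic data with the statistical structure of SNP-array CN studies.

The generator produces three tiers of data, each matched to the
assumptions of the corresponding pipeline stage:

* **reference panels** at the probe level: quartet PM/MM intensities for a
  genotyped diploid panel, with per-amplicon-size intensity scaling,
  uneven allele amplification (lognormal per-allele gains calibrated so
  the median of max(kA/kB, kB/kA) is ~1.4), and heteroscedastic quartet
  noise calibrated so the combined per-SNP variance has median ~0.0376;
* **samples** at the signal level: segment-structured integer CN along
  chromosomes, signals drawn as S(c) * exp(N(0, sigma)) under the
  contamination/ploidy model, with genotype annotations whose call rate
  and heterozygosity behave as CN dictates (near-absent calls at CN=0,
  near-zero heterozygosity at CN=1);
* **mixtures**: linear blending of a cancer and a diploid signal track at
  a stated benign fraction alpha, emulating DNA mixing before
  hybridization.

Evaluation utilities score calls against truth (false-alteration rate for
events spanning at least ``min_probes`` probes, probe-level concordance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import SampleModel, SignalCalibration, expected_signal

__all__ = [
    "NoiseSpec",
    "GenomeSpec",
    "default_genome",
    "implant_cnvs",
    "random_aneuploid_genome",
    "true_cn_per_probe",
    "simulate_reference_panel",
    "simulate_sample",
    "simulate_trio",
    "mix_samples",
    "evaluate_calls",
    "false_alteration_experiment",
    "contamination_experiment",
]

#: Discrete amplicon sizes (bp) used by the panel generator; restriction
#: fragments cluster, so a dozen well-populated size groups is realistic
#: and keeps the size-normalization groups dense.
AMPLICON_SIZES = np.linspace(100, 1143, 12).astype(int)

#: Genotype annotation behavior by true CN: (call probability,
#: heterozygote fraction among called).  Diploid regions call well and are
#: often heterozygous; CN=0 regions barely call; CN=1 regions call but are
#: nearly never heterozygous.
GENOTYPE_BEHAVIOR = {
    0: (0.35, 0.09),
    1: (0.90, 0.01),
    2: (0.93, 0.25),
}
GENOTYPE_BEHAVIOR_HIGH = (0.90, 0.20)  # CN >= 3


@dataclass
class NoiseSpec:
    """Noise levels of the generator.

    ``log_signal_sd`` is the per-probe sd of the natural-log signal.
    The default 0.097 puts the raw-scale variance of a diploid signal,
    mean (S_i - 2)^2 ~ 4 * log-variance, at ~0.0376 — the typical per-SNP
    panel variance the combination stage targets.  ``allelic_bias_sd`` is the sd of the
    lognormal per-allele gain; 0.353 per allele makes the median of
    max(kA/kB, kB/kA) ~1.4.  ``quartet_var_range`` bounds the uniform draw
    of per-quartet S_q variances; with six quartets the inverse-variance
    combination lands at median sigma_i^2 ~0.038.
    """

    log_signal_sd: float = 0.097
    allelic_bias_sd: float = 0.353
    quartet_var_range: tuple[float, float] = (0.08, 0.5)
    amplicon_effect_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.log_signal_sd < 0 or self.allelic_bias_sd < 0:
            raise ValueError("noise sds must be nonnegative")


@dataclass
class GenomeSpec:
    """Probe layout and true CN structure of one simulated genome.

    ``chromosomes`` is a list of dicts {name, n_snps, length_bp};
    ``segments`` is a list of dicts {chrom, start, end, cn} in probe-index
    coordinates (half-open) that tile each chromosome; probes not covered
    by any segment default to CN=2.  ``ploidy_factor`` records the
    genome-size factor beta the sample should be generated with.
    """

    chromosomes: list[dict]
    segments: list[dict] = field(default_factory=list)
    ploidy_factor: float = 1.0
    is_male: bool = False
    pseudoautosomal: list[tuple[int, int]] = field(default_factory=list)

    def probe_frame(self) -> pd.DataFrame:
        rows = []
        for ch in self.chromosomes:
            n = ch["n_snps"]
            step = ch["length_bp"] // (n + 1)
            for i in range(n):
                rows.append((f"{ch['name']}_snp{i:06d}", ch["name"], (i + 1) * step))
        return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def default_genome(
    n_autosomes: int = 4,
    snps_per_chrom: int = 5000,
    chrom_length: int = 150_000_000,
    include_x: bool = False,
    is_male: bool = False,
    ploidy_factor: float = 1.0,
) -> GenomeSpec:
    """A small test genome: ``n_autosomes`` chromosomes of equal probe
    density, optionally plus an X of the same size."""
    chroms = [
        {"name": str(i + 1), "n_snps": snps_per_chrom, "length_bp": chrom_length}
        for i in range(n_autosomes)
    ]
    if include_x:
        chroms.append({"name": "X", "n_snps": snps_per_chrom, "length_bp": chrom_length})
    return GenomeSpec(chromosomes=chroms, ploidy_factor=ploidy_factor, is_male=is_male)


def true_cn_per_probe(genome: GenomeSpec) -> np.ndarray:
    """Expand segments into a per-probe integer CN vector (probe order =
    ``genome.probe_frame()``).  Male X probes outside the pseudoautosomal
    intervals are forced to CN=1 (scaled by half for non-diploid X specs)."""
    sizes = {ch["name"]: ch["n_snps"] for ch in genome.chromosomes}
    offsets = {}
    off = 0
    for ch in genome.chromosomes:
        offsets[ch["name"]] = off
        off += ch["n_snps"]
    cn = np.full(off, 2, dtype=int)
    for seg in genome.segments:
        o = offsets[seg["chrom"]]
        cn[o + seg["start"] : o + seg["end"]] = seg["cn"]
    if genome.is_male and "X" in sizes:
        frame = genome.probe_frame()
        on_x = (frame["chrom"] == "X").to_numpy()
        pos = frame["pos"].to_numpy()
        in_par = np.zeros(off, dtype=bool)
        for lo, hi in genome.pseudoautosomal:
            in_par |= (pos >= lo) & (pos <= hi)
        cn[on_x & ~in_par] = 1
    return cn


def implant_cnvs(
    genome: GenomeSpec,
    rng: np.random.Generator,
    n_cnvs: int = 10,
    size_range: tuple[int, int] = (7, 50),
    cn_choices: tuple[int, ...] = (1, 3),
    autosomes_only: bool = True,
) -> GenomeSpec:
    """Return a copy of ``genome`` with non-overlapping CNV segments added."""
    chroms = [
        ch for ch in genome.chromosomes if not (autosomes_only and ch["name"] == "X")
    ]
    occupied: dict[str, list[tuple[int, int]]] = {ch["name"]: [] for ch in chroms}
    segs = list(genome.segments)
    placed = 0
    attempts = 0
    while placed < n_cnvs and attempts < 100 * n_cnvs:
        attempts += 1
        ch = chroms[rng.integers(len(chroms))]
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if size >= ch["n_snps"]:
            continue
        start = int(rng.integers(0, ch["n_snps"] - size))
        end = start + size
        if any(s < end and start < e for s, e in occupied[ch["name"]]):
            continue
        occupied[ch["name"]].append((start, end))
        segs.append(
            {"chrom": ch["name"], "start": start, "end": end,
             "cn": int(rng.choice(cn_choices))}
        )
        placed += 1
    if placed < n_cnvs:
        warnings.warn(f"implant_cnvs: placed only {placed}/{n_cnvs} CNVs")
    return replace(genome, segments=segs)


def random_aneuploid_genome(
    rng: np.random.Generator,
    n_chrom: int = 4,
    snps_per_chrom: int = 5000,
    cn_levels: tuple[int, ...] = (0, 1, 3, 4, 5, 6),
    level_weights: tuple[float, ...] = (0.04, 0.30, 0.30, 0.20, 0.10, 0.06),
    diploid_frac: float = 0.55,
    seg_size_range: tuple[int, int] = (800, 2500),
    focal_size_range: tuple[int, int] = (30, 120),
    ploidy_factor: float | None = None,
) -> GenomeSpec:
    """An aneuploid cancer-like genome: chromosomes tiled with segments.

    About ``diploid_frac`` of segments stay CN=2, so the diploid state
    dominates the smoothed-signal histogram as it does in real aneuploid
    lines; the remaining segments draw from ``cn_levels`` with weights
    skewed toward single-copy changes and away from extreme states.
    Homozygous deletions (CN=0) are focal — ``focal_size_range`` probes —
    since large zero-copy spans are not viable; other segments span
    ``seg_size_range`` probes, sized so that (as on real arrays, where a
    typical altered segment covers thousands of probes) only a few
    percent of probes sit in smoothing-transition zones whose
    intermediate values would otherwise seed spurious histogram modes.
    One segment of every level in ``cn_levels`` is guaranteed (placed
    first) so the full CN ladder is represented.  ``ploidy_factor``
    defaults to a draw in [0.9, 1.2]."""
    genome = default_genome(n_chrom, snps_per_chrom)
    if ploidy_factor is None:
        ploidy_factor = float(rng.uniform(0.9, 1.2))
    weights = np.asarray(level_weights, float)
    weights = weights / weights.sum()
    required = list(cn_levels)
    segs = []
    for ch in genome.chromosomes:
        pos = 0
        while pos < ch["n_snps"]:
            if rng.random() < diploid_frac:
                cn = 2
            elif required:
                cn = required.pop(0)
            else:
                cn = int(rng.choice(cn_levels, p=weights))
            lo, hi = focal_size_range if cn == 0 else seg_size_range
            size = int(rng.integers(lo, hi + 1))
            end = min(pos + size, ch["n_snps"])
            segs.append({"chrom": ch["name"], "start": pos, "end": end, "cn": cn})
            pos = end
    return replace(genome, segments=segs, ploidy_factor=ploidy_factor)


# ----------------------------------------------------------------------
# reference panel (probe level)
# ----------------------------------------------------------------------

def simulate_reference_panel(
    n_samples: int = 48,
    n_snps: int = 1000,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    n_quartets: int = 6,
    trio_structure: list[tuple[int, int, int]] | None = None,
    no_call_rate: float = 0.02,
    subarray: str = "Nsp",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Probe-level quartet intensities plus genotypes for a diploid panel.

    Genotypes are Hardy-Weinberg draws at per-SNP allele frequencies
    ~ Uniform(0.1, 0.9); with ``trio_structure`` (a list of (father,
    mother, child) sample indices) children inherit one parental allele
    each.  Intensities are built so the fitted pipeline recovers a diploid
    signal of 2: per-allele ideal intensity = allele dosage / k_allele,
    quartet noise with variance sigma_q^2 ~ U(quartet_var_range) on the
    S_q scale, then scaling by a per-(sample, amplicon-size) effect that
    size normalization must undo.

    Returns (probe_table, genotype_table, truth) where truth holds the
    generating k_A, k_B, allele frequencies, quartet variances, and
    amplicon sizes.
    """
    noise = noise or NoiseSpec()
    rng = rng or np.random.default_rng(0)

    snp_ids = np.array([f"snp{i:06d}" for i in range(n_snps)])
    positions = (np.arange(n_snps) + 1) * 1000
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    k_a = np.exp(rng.normal(0.0, noise.allelic_bias_sd, size=n_snps))
    k_b = np.exp(rng.normal(0.0, noise.allelic_bias_sd, size=n_snps))
    # keep each size group populated (~50 SNPs) so the per-sample group
    # mean is stable, as it is on real arrays with ~1e4 probes per size
    n_groups = int(np.clip(n_snps // 50, 1, len(AMPLICON_SIZES)))
    pool = AMPLICON_SIZES[np.linspace(0, len(AMPLICON_SIZES) - 1, n_groups).astype(int)]
    amp_sizes = rng.choice(pool, size=n_snps)
    lo, hi = noise.quartet_var_range
    sigma_q2 = rng.uniform(lo, hi, size=(n_snps, n_quartets))

    # allele counts of B per (snp, sample): 0 -> AA, 1 -> AB, 2 -> BB
    hap = (
        rng.random(size=(n_snps, n_samples, 2)) < freqs[:, None, None]
    ).astype(int)
    if trio_structure:
        for f, m, c in trio_structure:
            pick_f = rng.integers(0, 2, size=n_snps)
            pick_m = rng.integers(0, 2, size=n_snps)
            hap[:, c, 0] = hap[np.arange(n_snps), f, pick_f]
            hap[:, c, 1] = hap[np.arange(n_snps), m, pick_m]
    n_b = hap.sum(axis=2)
    dose_a = 2 - n_b
    dose_b = n_b

    # per-(sample, size) amplicon effect
    effect_by = {
        (s, int(sz)): rng.uniform(*noise.amplicon_effect_range)
        for s in range(n_samples)
        for sz in AMPLICON_SIZES
    }

    # per-allele noise scaled so var(S_q) = sigma_q^2 at the true gains
    tau = np.sqrt(sigma_q2 / (k_a ** 2 + k_b ** 2)[:, None])  # (snps, quartets)

    ideal_a = dose_a / k_a[:, None]  # (snps, samples)
    ideal_b = dose_b / k_b[:, None]

    n_rows = n_snps * n_samples * n_quartets * 2
    snp_col = np.repeat(snp_ids, n_samples * n_quartets * 2)
    chrom_col = np.full(n_rows, "1", dtype=object)
    pos_col = np.repeat(positions, n_samples * n_quartets * 2)
    sample_ids = np.array([f"panel{j:03d}" for j in range(n_samples)])
    sample_col = np.tile(np.repeat(sample_ids, n_quartets * 2), n_snps)
    quartet_col = np.tile(np.repeat(np.arange(1, n_quartets + 1), 2), n_snps * n_samples)
    allele_col = np.tile(np.array(["A", "B"]), n_snps * n_samples * n_quartets)

    # intensities in (snp, sample, quartet, allele) order
    eps = rng.normal(size=(n_snps, n_samples, n_quartets, 2)) * tau[:, None, :, None]
    intens = np.empty((n_snps, n_samples, n_quartets, 2))
    intens[..., 0] = ideal_a[:, :, None] + eps[..., 0]
    intens[..., 1] = ideal_b[:, :, None] + eps[..., 1]
    eff = np.array(
        [[effect_by[(j, int(amp_sizes[i]))] for j in range(n_samples)] for i in range(n_snps)]
    )
    delta_i = intens * eff[:, :, None, None]
    mm = rng.uniform(50.0, 150.0, size=delta_i.shape)
    pm = mm + delta_i

    probe_df = pd.DataFrame(
        {
            "snp_id": snp_col,
            "sample_id": sample_col,
            "chrom": chrom_col,
            "pos": pos_col,
            "quartet": quartet_col,
            "allele": allele_col,
            "pm": pm.ravel(),
            "mm": mm.ravel(),
            "amplicon_size": np.repeat(amp_sizes, n_samples * n_quartets * 2),
            "subarray": subarray,
        }
    )

    gt_name = np.array(["AA", "AB", "BB"])[n_b]
    nc = rng.random(size=gt_name.shape) < no_call_rate
    gt_name = gt_name.astype(object)
    gt_name[nc] = "NC"
    genotype_df = pd.DataFrame(
        {
            "snp_id": np.repeat(snp_ids, n_samples),
            "sample_id": np.tile(sample_ids, n_snps),
            "genotype": gt_name.ravel(),
        }
    )
    truth = {
        "k_a": k_a,
        "k_b": k_b,
        "freqs": freqs,
        "sigma_q2": sigma_q2,
        "amplicon_size": amp_sizes,
        "snp_ids": snp_ids,
        "sample_ids": sample_ids,
        "n_b": n_b,
    }
    return probe_df, genotype_df, truth


# ----------------------------------------------------------------------
# signal-level samples
# ----------------------------------------------------------------------

def _genotype_annotation(cn: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw per-SNP genotype calls consistent with the region CN."""
    n = cn.size
    p_call = np.empty(n)
    p_het = np.empty(n)
    for c in np.unique(cn):
        pc, ph = GENOTYPE_BEHAVIOR.get(int(c), GENOTYPE_BEHAVIOR_HIGH)
        sel = cn == c
        p_call[sel] = pc
        p_het[sel] = ph
    called = rng.random(n) < p_call
    het = rng.random(n) < p_het
    out = np.where(het, "AB", np.where(rng.random(n) < 0.5, "AA", "BB")).astype(object)
    out[~called] = "NC"
    return out


def simulate_sample(
    genome: GenomeSpec,
    model: SampleModel,
    cal: SignalCalibration | None = None,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One sample's per-SNP signal table with truth columns.

    Signals are ``S(true_cn; alpha, beta) * exp(N(0, log_signal_sd))``.
    Returns columns (snp_id, chrom, pos, signal, genotype, true_cn);
    callers wanting the genome's ploidy factor in the signals should pass
    a model with ``beta = genome.ploidy_factor``.
    """
    cal = cal or SignalCalibration()
    noise = noise or NoiseSpec()
    rng = rng or np.random.default_rng(0)
    frame = genome.probe_frame()
    cn = true_cn_per_probe(genome)
    mu = expected_signal(cn, model, cal)
    signal = mu * np.exp(rng.normal(0.0, noise.log_signal_sd, size=cn.size))
    frame["signal"] = signal
    frame["genotype"] = _genotype_annotation(cn, rng)
    frame["true_cn"] = cn
    return frame


def simulate_trio(
    base_genome: GenomeSpec,
    noise: NoiseSpec | None = None,
    cal: SignalCalibration | None = None,
    rng: np.random.Generator | None = None,
    n_cnvs_per_parent: int = 5,
    size_range: tuple[int, int] = (7, 50),
    cn_choices: tuple[int, ...] = (1, 3),
) -> dict[str, pd.DataFrame]:
    """Father/mother/child signal tables with Mendelian CNV inheritance.

    Each parent carries independent germline CNVs; each parental CNV is
    transmitted to the child with probability 1/2 (one haplotype drawn per
    event).  All three samples are diploid otherwise (normal mode).
    """
    noise = noise or NoiseSpec()
    cal = cal or SignalCalibration()
    rng = rng or np.random.default_rng(0)
    father = implant_cnvs(base_genome, rng, n_cnvs_per_parent, size_range, cn_choices)
    mother = implant_cnvs(base_genome, rng, n_cnvs_per_parent, size_range, cn_choices)
    child_segs = [s for s in father.segments + mother.segments if rng.random() < 0.5]
    child = replace(base_genome, segments=child_segs)
    model = SampleModel(mode="normal", sigma2=noise.log_signal_sd ** 2)
    return {
        "father": simulate_sample(father, model, cal, noise, rng),
        "mother": simulate_sample(mother, model, cal, noise, rng),
        "child": simulate_sample(child, model, cal, noise, rng),
    }


def mix_samples(
    cancer: pd.DataFrame,
    diploid: pd.DataFrame,
    alpha: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Blend two signal tables on the linear signal scale:
    ``(1 - alpha) * cancer + alpha * diploid`` (DNA quantity is additive).

    Probe sets must be identical and aligned.  Genotype annotations, when
    present in both tables, are resampled per SNP from the two sources
    with probabilities proportional to the DNA copies each contributes
    (a locus homozygously deleted in the cancer genome carries only
    normal-derived DNA, so it genotypes like the normal sample).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be within [0, 1]")
    if len(cancer) != len(diploid) or not (
        cancer["snp_id"].to_numpy() == diploid["snp_id"].to_numpy()
    ).all():
        raise ValueError("mix_samples: probe sets differ")
    out = cancer.copy()
    out["signal"] = (1.0 - alpha) * cancer["signal"].to_numpy() + alpha * diploid[
        "signal"
    ].to_numpy()
    if "genotype" in cancer.columns and "genotype" in diploid.columns:
        rng = rng or np.random.default_rng(0)
        cn = (
            cancer["true_cn"].to_numpy(float)
            if "true_cn" in cancer.columns
            else np.full(len(cancer), 2.0)
        )
        out["genotype"] = _mixture_genotypes(
            cancer["genotype"].to_numpy(), diploid["genotype"].to_numpy(),
            cn, alpha, rng,
        )
    out.attrs["mix_alpha"] = float(alpha)
    return out


#: Minor-allele fraction a genotype caller needs to report a heterozygote.
HET_CALL_FRACTION = 0.25


def _mixture_genotypes(
    g_cancer: np.ndarray,
    g_normal: np.ndarray,
    cn: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotype annotation of a DNA mixture from allele dosages.

    Each source contributes allele copies in proportion to its DNA
    fraction; the call is heterozygous only when the minor allele reaches
    ``HET_CALL_FRACTION`` of the locus's total copies (a caller keyed on
    allele ratios sees a 10% admixture as noise, not a genotype), and the
    call rate follows the total copy dose, so homozygously deleted loci
    genotype like the normal DNA that remains there.  No-call source
    genotypes contribute no allele information.
    """
    b_count = {"AA": 0.0, "AB": 1.0, "BB": 2.0, "NC": 0.0}
    b_c = np.vectorize(b_count.get)(g_cancer)
    b_n = np.vectorize(b_count.get)(g_normal)
    copies_cancer = (1.0 - alpha) * cn
    copies_normal = 2.0 * alpha
    b_copies = copies_cancer * b_c / 2.0 + copies_normal * b_n / 2.0
    total = copies_cancer + copies_normal
    b_frac = np.where(total > 0, b_copies / np.maximum(total, 1e-12), 0.0)
    minor = np.minimum(b_frac, 1.0 - b_frac)

    c_eff = np.clip(np.rint(total).astype(int), 0, None)
    p_call = np.array([
        GENOTYPE_BEHAVIOR.get(c, GENOTYPE_BEHAVIOR_HIGH)[0] for c in c_eff
    ])
    called = rng.random(cn.size) < p_call
    out = np.where(minor >= HET_CALL_FRACTION, "AB",
                   np.where(b_frac < 0.5, "AA", "BB")).astype(object)
    out[~called] = "NC"
    return out


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def _alteration_runs(cn: np.ndarray, chrom: np.ndarray, baseline: int):
    """Maximal runs of cn != baseline, never spanning chromosomes.
    Yields (start, end) half-open global indices."""
    alt = cn != baseline
    boundary = np.empty(cn.size, dtype=bool)
    boundary[0] = True
    boundary[1:] = chrom[1:] != chrom[:-1]
    runs = []
    i = 0
    n = cn.size
    while i < n:
        if alt[i]:
            j = i + 1
            while j < n and alt[j] and not boundary[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def evaluate_calls(
    truth: pd.DataFrame,
    calls: pd.DataFrame,
    min_probes: int = 7,
    baseline: int | None = None,
) -> dict:
    """Score a called CN track against truth on the same probe set.

    ``truth`` needs columns (chrom, true_cn) or (chrom, cn); ``calls``
    needs (chrom, cn).  Alterations are maximal runs differing from
    ``baseline`` (default: the modal true CN).  The false-alteration rate
    counts called alterations of >= ``min_probes`` probes that overlap no
    true alteration, plus true alterations of >= ``min_probes`` probes
    that overlap no call, as a percentage of all alterations considered
    (true events of >= ``min_probes`` plus spurious calls).  Concordance
    is the percentage of probes with identical CN.
    """
    t_cn = truth["true_cn" if "true_cn" in truth.columns else "cn"].to_numpy(int)
    c_cn = calls["cn"].to_numpy(int)
    if t_cn.size != c_cn.size:
        raise ValueError("probe sets differ")
    chrom = truth["chrom"].to_numpy()
    if baseline is None:
        baseline = int(np.bincount(t_cn).argmax())

    true_runs = _alteration_runs(t_cn, chrom, baseline)
    call_runs = _alteration_runs(c_cn, chrom, baseline)
    true_big = [r for r in true_runs if r[1] - r[0] >= min_probes]
    call_big = [r for r in call_runs if r[1] - r[0] >= min_probes]

    def overlaps(run, others):
        a, b = run
        return any(s < b and a < e for s, e in others)

    n_false = sum(1 for r in call_big if not overlaps(r, true_runs))
    n_missed = sum(1 for r in true_big if not overlaps(r, call_runs))
    denom = len(true_big) + n_false
    rate = 100.0 * (n_false + n_missed) / denom if denom else 0.0
    return {
        "false_alteration_rate": rate,
        "concordance": 100.0 * float(np.mean(t_cn == c_cn)),
        "n_true_alterations": len(true_big),
        "n_called_alterations": len(call_big),
        "n_false_called": n_false,
        "n_missed_true": n_missed,
    }


# ----------------------------------------------------------------------
# benchmark experiments (germline false-call rate; contamination series)
# ----------------------------------------------------------------------

def false_alteration_experiment(
    seed: int,
    n_genomes: int = 20,
    n_chrom: int = 4,
    snps_per_chrom: int = 5000,
    n_cnvs: int = 10,
    size_range: tuple[int, int] = (7, 50),
    cn_choices: tuple[int, ...] = (1, 3),
    noise: NoiseSpec | None = None,
    min_probes: int = 7,
) -> dict:
    """Germline false-call benchmark on simulated normal genomes.

    Each replicate implants ``n_cnvs`` germline CNVs into a diploid
    genome, simulates signals at the default noise level, runs the full
    calling pipeline in normal mode, and scores spurious plus missed
    alterations of at least ``min_probes`` probes.  Returns the combined
    rate (percent of all such alterations) pooled over replicates.
    """
    from .pipeline import RunConfig, run_call_pipeline

    noise = noise or NoiseSpec()
    tot_false = tot_missed = tot_true = 0
    per_genome = []
    n_probes_total = 0
    for g in range(n_genomes):
        rng = np.random.default_rng([seed, g])
        genome = implant_cnvs(
            default_genome(n_chrom, snps_per_chrom), rng,
            n_cnvs=n_cnvs, size_range=size_range, cn_choices=cn_choices,
        )
        model = SampleModel(mode="normal", sigma2=noise.log_signal_sd ** 2)
        df = simulate_sample(genome, model, noise=noise, rng=rng)
        res = run_call_pipeline(df, RunConfig(mode="normal"))
        ev = evaluate_calls(df, res.segmentation.probes, min_probes=min_probes)
        tot_false += ev["n_false_called"]
        tot_missed += ev["n_missed_true"]
        tot_true += ev["n_true_alterations"]
        n_probes_total += len(df)
        per_genome.append(ev)
    denom = tot_true + tot_false
    rate = 100.0 * (tot_false + tot_missed) / denom if denom else 0.0
    return {
        "false_alteration_rate": rate,
        "n_true_alterations": tot_true,
        "n_false_called": tot_false,
        "n_missed_true": tot_missed,
        "n_probes": n_probes_total,
        "per_genome": per_genome,
    }


def contamination_experiment(
    seed: int,
    alphas: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    n_chrom: int = 4,
    snps_per_chrom: int = 5000,
    noise: NoiseSpec | None = None,
) -> dict:
    """Benign-contamination benchmark: call an aneuploid genome pure and
    in diploid mixtures, then compare.

    One aneuploid genome (segmented CN 0-6, genome-size factor drawn in
    [0.9, 1.2]) is simulated as a pure cancer sample and mixed with a
    matched diploid sample at each ``alpha``.  The pipeline runs in
    cell-line mode on the pure sample and tumor mode on each mixture.
    Reports per-alpha probe-level concordance of mixture calls against the
    pure calls, the estimated contamination, the minimum concordance over
    the series, and the mean absolute error of the alpha estimates.
    """
    from .pipeline import RunConfig, run_call_pipeline

    noise = noise or NoiseSpec()
    rng = np.random.default_rng([seed, 1000])
    genome = random_aneuploid_genome(rng, n_chrom=n_chrom, snps_per_chrom=snps_per_chrom)
    cancer = simulate_sample(
        genome,
        SampleModel(0.0, genome.ploidy_factor, noise.log_signal_sd ** 2, "cell_line"),
        noise=noise, rng=rng,
    )
    diploid = simulate_sample(
        default_genome(n_chrom, snps_per_chrom),
        SampleModel(mode="normal", sigma2=noise.log_signal_sd ** 2),
        noise=noise, rng=rng,
    )
    pure = run_call_pipeline(cancer, RunConfig(mode="cell_line"))
    per_alpha = {}
    for i, alpha in enumerate(alphas):
        mix_rng = np.random.default_rng([seed, 2000 + i])
        mixed = mix_samples(cancer, diploid, alpha, rng=mix_rng)
        res = run_call_pipeline(mixed, RunConfig(mode="tumor"))
        conc = evaluate_calls(pure.segmentation.probes, res.segmentation.probes)[
            "concordance"
        ]
        per_alpha[alpha] = {
            "concordance": conc,
            "alpha_hat": res.segmentation.sample_model.alpha,
            "beta_hat": res.segmentation.sample_model.beta,
        }
    concs = [v["concordance"] for v in per_alpha.values()]
    errs = [abs(v["alpha_hat"] - a) for a, v in per_alpha.items()]
    return {
        "min_concordance": min(concs),
        "mean_abs_alpha_error": float(np.mean(errs)),
        "ploidy_factor": genome.ploidy_factor,
        "pure_beta_hat": pure.segmentation.sample_model.beta,
        "n_probes": len(cancer),
        "per_alpha": per_alpha,
    }
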