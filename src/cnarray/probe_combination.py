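"""Combine quartet-level PM/MM probe intensities into one signal per SNP.

A 500K-style genotyping array interrogates each SNP with 6 or 10 probe
quartets (perfect-match and mismatch 25-mers for both alleles), sitting on
restriction-digest PCR amplicons whose size strongly modulates intensity.
This module implements the normalization chain that turns those raw
intensities into a single per-SNP signal ``S_i`` whose expectation is 2 at
diploid copy number:

1. background subtraction ``dI = I_PM - I_MM`` and division by the mean
   ``dI`` of all probes on amplicons of the same size (per subarray);
2. allele combination ``S_q = k_A * I_qA + k_B * I_qB`` with per-SNP
   parameters fitted on a genotyped reference panel of diploid samples so
   that S_q is close to 2 whatever the genotype — the ratio k_A/k_B
   captures uneven allele amplification;
3. inverse-variance weighting of quartets, ``S_i = sum_q w_q S_q`` with
   ``w_q`` proportional to ``1/sigma_q^2`` estimated across the panel;
4. quality filtering on the panel variance of S_i, and averaging of SNPs
   sharing one amplicon (copy-number changes cannot differ within an
   amplicon, so they carry one signal).

All tabular inputs/outputs are pandas DataFrames in the TSV dialects of
:mod:`cnarray.io`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpProbeSet",
    "ReferencePanel",
    "PanelFit",
    "size_normalize",
    "allele_params_closed_form",
    "estimate_allele_params",
    "fit_quartet_weights",
    "combine_to_snp_signal",
    "qc_filter",
    "merge_amplicon_groups",
    "fit_reference_panel",
]

logger = logging.getLogger(__name__)

X_CHROM_NAMES = frozenset({"X", "chrX", "x", "23"})

#: Panel variance cutoff above which a SNP is dropped from CN analysis.
VARIANCE_CUTOFF = 0.25

#: Minimum quartet observations for an amplicon-size group to stand alone;
#: sparser sizes are pooled with the nearest size.
MIN_GROUP_OBS = 20

VARIANCE_FLOOR = 1e-6


@dataclass
class SnpProbeSet:
    """Fitted per-SNP combination parameters."""

    snp_id: str
    chromosome: str
    position_bp: int
    k_a: float = np.nan
    k_b: float = np.nan
    quartet_weights: dict[int, float] = field(default_factory=dict)
    quartet_variances: dict[int, float] = field(default_factory=dict)
    combined_variance: float = np.nan       # 1 / sum(1/sigma_q^2)
    equal_weight_variance: float = np.nan   # (1/n) sum sigma_q^2
    panel_variance: float = np.nan          # mean (S_i - 2)^2 over panel
    n_quartets: int = 0
    excluded: bool = False
    exclusion_reason: str | None = None
    amplicon_group_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "snp_id": self.snp_id,
            "chromosome": self.chromosome,
            "position_bp": int(self.position_bp),
            "k_a": None if np.isnan(self.k_a) else self.k_a,
            "k_b": None if np.isnan(self.k_b) else self.k_b,
            "quartet_weights": {str(q): w for q, w in self.quartet_weights.items()},
            "quartet_variances": {str(q): v for q, v in self.quartet_variances.items()},
            "combined_variance": None if np.isnan(self.combined_variance) else self.combined_variance,
            "equal_weight_variance": None if np.isnan(self.equal_weight_variance) else self.equal_weight_variance,
            "panel_variance": None if np.isnan(self.panel_variance) else self.panel_variance,
            "n_quartets": self.n_quartets,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "amplicon_group_id": self.amplicon_group_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SnpProbeSet":
        nan = float("nan")
        return cls(
            snp_id=d["snp_id"],
            chromosome=d["chromosome"],
            position_bp=int(d["position_bp"]),
            k_a=nan if d.get("k_a") is None else float(d["k_a"]),
            k_b=nan if d.get("k_b") is None else float(d["k_b"]),
            quartet_weights={int(q): float(w) for q, w in d.get("quartet_weights", {}).items()},
            quartet_variances={int(q): float(v) for q, v in d.get("quartet_variances", {}).items()},
            combined_variance=nan if d.get("combined_variance") is None else float(d["combined_variance"]),
            equal_weight_variance=nan if d.get("equal_weight_variance") is None else float(d["equal_weight_variance"]),
            panel_variance=nan if d.get("panel_variance") is None else float(d["panel_variance"]),
            n_quartets=int(d.get("n_quartets", 0)),
            excluded=bool(d.get("excluded", False)),
            exclusion_reason=d.get("exclusion_reason"),
            amplicon_group_id=d.get("amplicon_group_id"),
        )


@dataclass
class ReferencePanel:
    """A genotyped panel of diploid samples used to fit probe parameters.

    ``samples`` maps sample_id -> sex ("F"/"M"); ``genotypes`` is a long
    DataFrame (snp_id, sample_id, genotype in {AA, AB, BB, NC});
    ``intensities`` is the raw probe table (see :func:`cnarray.io.read_probe_table`).
    ``pseudoautosomal`` lists (start, end) 1-based inclusive intervals on X
    that stay diploid in males.
    """

    samples: Mapping[str, str]
    genotypes: pd.DataFrame
    intensities: pd.DataFrame
    pseudoautosomal: Sequence[tuple[int, int]] = ()

    def female_samples(self) -> list[str]:
        return [s for s, sex in self.samples.items() if str(sex).upper().startswith("F")]


def _lower_median(values: np.ndarray) -> float:
    """Median with the lower-of-two convention for even counts (deterministic)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return float("nan")
    return float(v[(v.size - 1) // 2])


def _effective_size_map(counts: pd.Series, min_obs: int) -> dict:
    """Map amplicon size -> effective group size, pooling sizes with fewer
    than ``min_obs`` observations into the nearest well-populated size."""
    sizes = np.array(sorted(counts.index))
    good = np.array([s for s in sizes if counts[s] >= min_obs])
    mapping = {}
    for s in sizes:
        if counts[s] >= min_obs or good.size == 0:
            mapping[s] = s
        else:
            # nearest well-populated size; ties resolve to the smaller size
            d = np.abs(good - s)
            mapping[s] = int(good[np.argmin(d)])
    return mapping


def size_normalize(
    records: pd.DataFrame,
    min_group_obs: int = MIN_GROUP_OBS,
) -> pd.DataFrame:
    """Amplicon-size normalization of background-corrected intensities.

    For every record ``dI = pm - mm``; within each (sample, subarray,
    amplicon-size) group the mean ``dI_s`` is taken over all quartets and
    alleles, and the normalized intensity ``dI / dI_s`` is returned in a new
    column ``inorm``.  Negative ``dI`` propagates through (clamping happens
    later, before logs).  Size groups with mean ``dI_s <= 0`` are unusable:
    their rows are dropped with a warning.
    """
    if len(records) == 0:
        raise ValueError("size_normalize: empty probe table")
    df = records.copy()
    df["_di"] = df["pm"].to_numpy(float) - df["mm"].to_numpy(float)

    keys = ["sample_id", "subarray"] if "sample_id" in df.columns else ["subarray"]
    # pool sparse amplicon sizes (mapping shared across samples per subarray)
    n_samples = df["sample_id"].nunique() if "sample_id" in df.columns else 1
    eff = np.empty(len(df), dtype=int)
    for sub, idx in df.groupby("subarray", sort=False).groups.items():
        counts = df.loc[idx, "amplicon_size"].value_counts() / n_samples
        mapping = _effective_size_map(counts, min_group_obs)
        eff[df.index.get_indexer(idx)] = df.loc[idx, "amplicon_size"].map(mapping).to_numpy()
    df["_eff_size"] = eff

    grp = df.groupby(keys + ["_eff_size"], sort=False)["_di"]
    means = grp.transform("mean")
    bad = means <= 0
    if bad.any():
        bad_sizes = sorted(df.loc[bad, "_eff_size"].unique())
        warnings.warn(
            f"size_normalize: {int(bad.sum())} probes in amplicon-size groups "
            f"{bad_sizes} with non-positive mean dI excluded"
        )
    df["inorm"] = df["_di"] / means.where(~bad)
    out = df.loc[~bad].drop(columns=["_di", "_eff_size"])
    return out


def allele_params_closed_form(
    n_by_gt: Mapping[str, float],
    x_by_gt: Mapping[str, float],
    y_by_gt: Mapping[str, float],
) -> tuple[float, float]:
    """Closed-form minimizer of the panel calibration objective

        E(kA, kB) = sum_gt N_gt * (kA*x_gt + kB*y_gt - 2)^2

    over genotype classes gt in {AA, AB, BB}; ``x``/``y`` are the panel
    medians of the A/B-allele normalized intensities per class.

    Raises ``ZeroDivisionError`` on a degenerate design matrix.
    """
    gts = [g for g in ("AA", "AB", "BB") if n_by_gt.get(g, 0) > 0]
    n = np.array([n_by_gt[g] for g in gts], dtype=float)
    x = np.array([x_by_gt[g] for g in gts], dtype=float)
    y = np.array([y_by_gt[g] for g in gts], dtype=float)
    c_x = float(np.sum(n * x))
    c_y = float(np.sum(n * y))
    c_xy = float(np.sum(n * x * y))
    c_xx = float(np.sum(n * x * x))
    c_yy = float(np.sum(n * y * y))
    den = c_xx * c_yy - c_xy * c_xy
    scale = max(c_xx * c_yy, c_xy * c_xy, 1.0)
    if abs(den) <= 1e-12 * scale:
        raise ZeroDivisionError("degenerate design")
    k_a = 2.0 * (c_x * c_yy - c_y * c_xy) / den
    k_b = 2.0 * (c_y * c_xx - c_x * c_xy) / den
    return k_a, k_b


def _is_x_chrom(chrom: str) -> bool:
    return str(chrom) in X_CHROM_NAMES


def _in_par(pos: int, par: Sequence[tuple[int, int]]) -> bool:
    return any(lo <= pos <= hi for lo, hi in par)


def estimate_allele_params(panel: ReferencePanel, snp_id: str) -> tuple[float, float]:
    """Fit (k_A, k_B) for one SNP from panel medians.

    For X-chromosome SNPs outside the pseudoautosomal regions only female
    panel samples are used (males carry one X, breaking the CN=2
    assumption).  Raises ``ValueError`` for monomorphic or degenerate SNPs.
    """
    ints = panel.intensities
    rows = ints[ints["snp_id"] == snp_id]
    if len(rows) == 0:
        raise ValueError(f"no intensities for SNP {snp_id}")
    if "inorm" not in rows.columns:
        rows = size_normalize(rows)
    chrom = rows["chrom"].iloc[0]
    pos = int(rows["pos"].iloc[0])
    if _is_x_chrom(chrom) and not _in_par(pos, panel.pseudoautosomal):
        females = set(panel.female_samples())
        rows = rows[rows["sample_id"].isin(females)]
    gt = panel.genotypes
    gt = gt[(gt["snp_id"] == snp_id) & gt["genotype"].isin(["AA", "AB", "BB"])]
    gt_map = dict(zip(gt["sample_id"], gt["genotype"]))
    rows = rows[rows["sample_id"].isin(gt_map)]
    if rows.empty:
        raise ValueError(f"SNP {snp_id}: no genotyped samples with intensities")
    gclass = rows["sample_id"].map(gt_map)
    observed = sorted(set(gclass))
    if len(observed) < 2:
        raise ValueError(f"SNP {snp_id}: monomorphic in panel")
    n_by, x_by, y_by = {}, {}, {}
    for g in observed:
        sub = rows[gclass == g]
        n_by[g] = sub["sample_id"].nunique()
        x_by[g] = _lower_median(sub.loc[sub["allele"] == "A", "inorm"].to_numpy())
        y_by[g] = _lower_median(sub.loc[sub["allele"] == "B", "inorm"].to_numpy())
    try:
        return allele_params_closed_form(n_by, x_by, y_by)
    except ZeroDivisionError as exc:
        raise ValueError(f"SNP {snp_id}: degenerate design") from exc


def fit_quartet_weights(
    sq_by_quartet: Mapping[int, np.ndarray] | Mapping[int, float],
    variance_floor: float = VARIANCE_FLOOR,
) -> tuple[dict[int, float], dict[int, float], float, float]:
    """Inverse-variance quartet weights.

    ``sq_by_quartet`` maps quartet index to either the vector of S_q values
    across panel samples or directly to a variance.  Returns
    ``(weights, variances, combined_variance, equal_weight_variance)`` with
    ``w_q ∝ 1/sigma_q^2`` normalized to 1, ``sigma_i^2 = 1/sum(1/sigma_q^2)``
    and the equal-weight benchmark ``s_i^2 = mean(sigma_q^2)``.
    """
    variances: dict[int, float] = {}
    for q, v in sq_by_quartet.items():
        arr = np.asarray(v, dtype=float)
        var = float(np.var(arr, ddof=1)) if arr.ndim > 0 and arr.size > 1 else float(arr)
        if var <= 0:
            warnings.warn(f"quartet {q}: zero variance floored at {variance_floor}")
            var = variance_floor
        variances[int(q)] = var
    inv = {q: 1.0 / v for q, v in variances.items()}
    tot = sum(inv.values())
    weights = {q: iv / tot for q, iv in inv.items()}
    combined = 1.0 / tot
    equal = float(np.mean(list(variances.values())))
    return weights, variances, combined, equal


def combine_to_snp_signal(
    intensities: Mapping[tuple[int, str], float],
    probe_set: SnpProbeSet,
) -> float:
    """Combine one sample's normalized intensities for one SNP into S_i.

    ``intensities`` maps (quartet_index, allele) -> normalized intensity.
    Quartets missing either allele are dropped and the remaining weights
    renormalized (with a warning).
    """
    s_q: dict[int, float] = {}
    for q in probe_set.quartet_weights:
        if (q, "A") in intensities and (q, "B") in intensities:
            s_q[q] = probe_set.k_a * intensities[(q, "A")] + probe_set.k_b * intensities[(q, "B")]
    if not s_q:
        raise ValueError(f"SNP {probe_set.snp_id}: no complete quartets")
    if len(s_q) < len(probe_set.quartet_weights):
        warnings.warn(
            f"SNP {probe_set.snp_id}: {len(probe_set.quartet_weights) - len(s_q)} "
            "missing quartets; weights renormalized"
        )
    w_tot = sum(probe_set.quartet_weights[q] for q in s_q)
    return sum(probe_set.quartet_weights[q] * s for q, s in s_q.items()) / w_tot


def qc_filter(
    probe_sets: Mapping[str, SnpProbeSet],
    panel_signals: pd.DataFrame,
    cutoff: float = VARIANCE_CUTOFF,
) -> dict[str, SnpProbeSet]:
    """Exclude SNPs whose panel variance mean (S_i - 2)^2 exceeds ``cutoff``.

    ``panel_signals`` is long-form (snp_id, sample_id, signal).  Exclusions
    already present (monomorphic/degenerate) are preserved.
    """
    var = (
        panel_signals.assign(_d=(panel_signals["signal"] - 2.0) ** 2)
        .groupby("snp_id")["_d"]
        .mean()
    )
    out = {}
    n_excl = 0
    for snp_id, ps in probe_sets.items():
        ps.panel_variance = float(var.get(snp_id, np.nan))
        if not ps.excluded and ps.panel_variance > cutoff:
            ps.excluded = True
            ps.exclusion_reason = "high_variance"
            n_excl += 1
        out[snp_id] = ps
    if n_excl:
        logger.info("qc_filter: %d SNPs excluded with panel variance > %g", n_excl, cutoff)
    return out


def merge_amplicon_groups(signal_df: pd.DataFrame, group_of: Mapping[str, str]) -> pd.DataFrame:
    """Average signals of SNPs sharing a PCR amplicon.

    CN changes affect a whole amplicon, so its SNPs carry one signal: the
    group mean is assigned to the lowest-position SNP and the others are
    dropped.  SNPs absent from ``group_of`` pass through unchanged.
    """
    df = signal_df.copy()
    df["_grp"] = df["snp_id"].map(lambda s: group_of.get(s, f"__solo_{s}"))
    keys = [c for c in ("sample_id",) if c in df.columns] + ["_grp"]
    df["signal"] = df.groupby(keys)["signal"].transform("mean")
    df = df.sort_values("pos", kind="stable").drop_duplicates(subset=keys, keep="first")
    order = [c for c in ("sample_id", "chrom", "pos") if c in df.columns]
    return df.drop(columns="_grp").sort_values(order, kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
# whole-panel fit
# ----------------------------------------------------------------------

@dataclass
class PanelFit:
    """Result of :func:`fit_reference_panel`."""

    probe_sets: dict[str, SnpProbeSet]
    panel_signals: pd.DataFrame  # snp_id, sample_id, signal (pre-QC, pre-merge)

    def retained(self) -> list[str]:
        return [s for s, ps in self.probe_sets.items() if not ps.excluded]

    def to_dict(self) -> dict:
        return {"probe_sets": [ps.to_dict() for ps in self.probe_sets.values()]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelFit":
        sets = {p["snp_id"]: SnpProbeSet.from_dict(p) for p in d["probe_sets"]}
        return cls(probe_sets=sets, panel_signals=pd.DataFrame(columns=["snp_id", "sample_id", "signal"]))


def fit_reference_panel(
    panel: ReferencePanel,
    variance_cutoff: float = VARIANCE_CUTOFF,
    min_group_obs: int = MIN_GROUP_OBS,
) -> PanelFit:
    """Fit allele parameters, quartet weights and QC flags for every SNP.

    Vectorized over the whole panel: size-normalize intensities, compute
    per-genotype medians, apply the closed-form (k_A, k_B), estimate quartet
    variances of S_q across samples, build inverse-variance weights, combine
    to S_i, and flag monomorphic / degenerate / high-variance SNPs.
    """
    ints = size_normalize(panel.intensities, min_group_obs=min_group_obs)
    gt = panel.genotypes
    called = gt[gt["genotype"].isin(["AA", "AB", "BB"])]
    gt_key = called.set_index(["snp_id", "sample_id"])["genotype"]

    meta = ints.groupby("snp_id", sort=False).agg(
        chrom=("chrom", "first"), pos=("pos", "first")
    )
    amp_col = ints.groupby("snp_id", sort=False)["amplicon_id"].first() if "amplicon_id" in ints.columns else None

    females = set(panel.female_samples())

    probe_sets: dict[str, SnpProbeSet] = {}
    sig_rows = []
    # per-SNP loop: panel fitting is a one-off calibration step
    for snp_id, sub in ints.groupby("snp_id", sort=False):
        chrom = sub["chrom"].iloc[0]
        pos = int(sub["pos"].iloc[0])
        ps = SnpProbeSet(
            snp_id=snp_id,
            chromosome=str(chrom),
            position_bp=pos,
            amplicon_group_id=str(amp_col[snp_id]) if amp_col is not None else None,
        )
        fit_sub = sub
        if _is_x_chrom(chrom) and not _in_par(pos, panel.pseudoautosomal):
            fit_sub = sub[sub["sample_id"].isin(females)]
        try:
            gclass = pd.MultiIndex.from_arrays(
                [fit_sub["snp_id"], fit_sub["sample_id"]]
            ).map(gt_key)
        except Exception:
            gclass = pd.Series(index=fit_sub.index, dtype=object)
        fit_sub = fit_sub.assign(_gt=np.asarray(gclass)).dropna(subset=["_gt"])
        observed = sorted(set(fit_sub["_gt"]))
        if len(observed) < 2:
            ps.excluded, ps.exclusion_reason = True, "monomorphic"
            probe_sets[snp_id] = ps
            continue
        n_by, x_by, y_by = {}, {}, {}
        for g in observed:
            gs = fit_sub[fit_sub["_gt"] == g]
            n_by[g] = gs["sample_id"].nunique()
            x_by[g] = _lower_median(gs.loc[gs["allele"] == "A", "inorm"].to_numpy())
            y_by[g] = _lower_median(gs.loc[gs["allele"] == "B", "inorm"].to_numpy())
        try:
            ps.k_a, ps.k_b = allele_params_closed_form(n_by, x_by, y_by)
        except ZeroDivisionError:
            ps.excluded, ps.exclusion_reason = True, "degenerate_design"
            probe_sets[snp_id] = ps
            continue

        # S_q per (sample, quartet) from ALL samples (parameters fixed now)
        wide = sub.pivot_table(
            index=["sample_id", "quartet"], columns="allele", values="inorm", aggfunc="first"
        )
        if "A" not in wide.columns or "B" not in wide.columns:
            ps.excluded, ps.exclusion_reason = True, "missing_allele"
            probe_sets[snp_id] = ps
            continue
        wide = wide.dropna(subset=["A", "B"])
        s_q = ps.k_a * wide["A"] + ps.k_b * wide["B"]
        sq_by_quartet = {
            int(q): grp.to_numpy() for q, grp in s_q.groupby(level="quartet")
        }
        ps.quartet_weights, ps.quartet_variances, ps.combined_variance, ps.equal_weight_variance = (
            fit_quartet_weights(sq_by_quartet)
        )
        ps.n_quartets = len(ps.quartet_weights)
        w = s_q.index.get_level_values("quartet").map(ps.quartet_weights).to_numpy(float)
        si = (s_q * w).groupby(level="sample_id").sum() / pd.Series(w, index=s_q.index).groupby(
            level="sample_id"
        ).sum()
        for sample_id, s in si.items():
            sig_rows.append((snp_id, sample_id, float(s)))
        probe_sets[snp_id] = ps

    panel_signals = pd.DataFrame(sig_rows, columns=["snp_id", "sample_id", "signal"])
    probe_sets = qc_filter(probe_sets, panel_signals, cutoff=variance_cutoff)
    return PanelFit(probe_sets=probe_sets, panel_signals=panel_signals)


def combine_sample(
    probe_df: pd.DataFrame,
    fit: PanelFit,
    min_group_obs: int = MIN_GROUP_OBS,
) -> pd.DataFrame:
    """Produce the per-SNP signal table for one sample using fitted parameters.

    Returns columns (snp_id, chrom, pos, signal) for retained SNPs, with
    SNPs sharing an amplicon averaged onto the lowest-position member.
    """
    ints = size_normalize(probe_df, min_group_obs=min_group_obs)
    rows = []
    for snp_id, sub in ints.groupby("snp_id", sort=False):
        ps = fit.probe_sets.get(snp_id)
        if ps is None or ps.excluded:
            continue
        pairs = {
            (int(q), a): v
            for q, a, v in zip(sub["quartet"], sub["allele"], sub["inorm"])
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                s_i = combine_to_snp_signal(pairs, ps)
            except ValueError:
                continue
        rows.append((snp_id, ps.chromosome, ps.position_bp, s_i))
    out = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "signal"])
    group_of = {
        s: ps.amplicon_group_id
        for s, ps in fit.probe_sets.items()
        if ps.amplicon_group_id is not None
    }
    if group_of:
        out = merge_amplicon_groups(out, group_of)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
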