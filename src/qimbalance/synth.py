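"""Synthetic case/control sequencing datasets with known ground truth.

The generator emulates the statistical structure the quality-imbalance
analysis assumes:

* two patient groups (control / disease);
* a latent per-sample quality ``q in [0, 1]`` reported directly as P_low
  (the quality classifier is treated as a perfect probe of q);
* negative-binomial counts with log2-linear gene effects::

      K_ij ~ NB(mean = s_i * b_j * 2**(beta_dis_j * g_i + beta_q_j * q_i
                                       + pair effect), dispersion alpha_j)

  where ``s_i`` is a log-normal size factor, ``b_j`` a log-normal baseline,
  ``g_i`` the 0/1 group code;
* planted *low-quality marker* genes (``beta_q > 0``: expression rises with
  P_low), *high-quality markers* (``beta_q < 0``), and *disease genes*
  (``beta_dis != 0``, random sign, magnitude varied around the configured
  effect so the planted disease genes form a ranked list);
* a tunable quality-group confounding level ``qi_target``: group-wise Beta
  distributions for q whose mean difference is calibrated by bisection so
  the expected point-biserial QI index matches the target;
* optional one-to-one sample pairing with a shared per-pair, per-gene
  effect, and optional planted quality-outlier samples.

Everything is driven by a single integer seed: identical ``SimConfig``
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import qi
from .exceptions import CalibrationError

_Q_MEAN = 0.5        # pooled mean of latent quality
_Q_MARGIN = 0.02     # group Beta means stay within [margin, 1-margin]
_QI_TOL = 0.02       # bisection tolerance on the expected QI index


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``dispersion_shape`` is the (shape, scale) of the Gamma distribution the
    per-gene NB dispersions alpha_j are drawn from; ``libsize_sd`` the
    log-scale spread of size factors; ``quality_concentration`` the Beta
    concentration of latent quality within each group (smaller = broader
    spread of P_low); ``quality_effect`` / ``disease_effect`` the log2-scale
    magnitudes e and d of planted per-gene effects.
    """

    n_control: int = 10
    n_disease: int = 10
    n_genes: int = 2000
    n_low_markers: int = 150
    n_high_markers: int = 150
    n_disease_genes: int = 100
    quality_effect: float = 2.0
    disease_effect: float = 2.0
    qi_target: float = 0.2
    dispersion_shape: tuple[float, float] = (2.0, 0.05)
    libsize_sd: float = 0.2
    quality_concentration: float = 10.0
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    pair_sd: float = 0.3
    n_outliers: int = 0
    outlier_p_low: float = 0.95
    paired: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 2 or self.n_disease < 2:
            raise ValueError("need at least 2 samples per group")
        planted = self.n_low_markers + self.n_high_markers + self.n_disease_genes
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.qi_target <= 1.0:
            raise ValueError("qi_target must lie in [0, 1]")
        if self.quality_effect < 0 or self.disease_effect < 0:
            raise ValueError("effect magnitudes must be >= 0")
        if min(self.n_low_markers, self.n_high_markers, self.n_disease_genes,
               self.n_outliers) < 0:
            raise ValueError("gene/sample counts must be >= 0")
        if self.paired and self.n_control != self.n_disease:
            raise ValueError("paired design requires equal group sizes")
        for name in ("quality_effect", "disease_effect", "libsize_sd",
                     "quality_concentration", "baseline_log_sd", "pair_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset.

    ``genes`` has one row per gene: role in {low_marker, high_marker,
    disease, null}, signed log2-scale coefficients ``beta_quality`` and
    ``beta_disease``. ``sample_truth`` has latent quality and size factor
    per sample. ``realized_qi`` is the point-biserial QI index of the
    emitted dataset.
    """

    genes: pd.DataFrame
    sample_truth: pd.DataFrame
    realized_qi: float
    bins: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# QI calibration


def _group_beta_params(delta: float, kappa: float) -> tuple[float, float, float, float]:
    mu0 = _Q_MEAN - delta / 2.0
    mu1 = _Q_MEAN + delta / 2.0
    return mu0 * kappa, (1 - mu0) * kappa, mu1 * kappa, (1 - mu1) * kappa


def expected_qi(delta: float, kappa: float, n0: int, n1: int) -> float:
    """Population point-biserial correlation for a group mean gap ``delta``.

    Latent quality is Beta(mean 0.5 -/+ delta/2, concentration kappa) per
    group; with group proportion p = n1/n the point-biserial of the mixture is
    ``delta * sqrt(p(1-p)) / sigma_total``.
    """
    n = n0 + n1
    p = n1 / n
    mu0 = _Q_MEAN - delta / 2.0
    mu1 = _Q_MEAN + delta / 2.0
    var0 = mu0 * (1 - mu0) / (kappa + 1)
    var1 = mu1 * (1 - mu1) / (kappa + 1)
    total_var = (1 - p) * var0 + p * var1 + p * (1 - p) * delta**2
    return delta * np.sqrt(p * (1 - p)) / np.sqrt(total_var)


def calibrate_quality_gap(qi_target: float, kappa: float, n0: int, n1: int,
                          tol: float = _QI_TOL) -> float:
    """Bisect the group quality-mean gap to reach an expected QI index.

    Raises ``CalibrationError`` (with the achievable bound) when the target
    exceeds what the Beta family can produce at this concentration.
    """
    if qi_target == 0:
        return 0.0
    delta_max = 1.0 - 2.0 * _Q_MARGIN
    reachable = expected_qi(delta_max, kappa, n0, n1)
    if qi_target > reachable + tol:
        raise CalibrationError(
            f"qi_target={qi_target} unreachable; achievable QI <= {reachable:.3f} "
            f"at quality_concentration={kappa}",
            achievable=float(reachable),
        )
    lo, hi = 0.0, delta_max
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = expected_qi(mid, kappa, n0, n1)
        if abs(val - qi_target) <= tol:
            return mid
        if val < qi_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Dataset simulation


def _draw_quality(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-sample latent quality; control block first, then disease."""
    delta = calibrate_quality_gap(
        config.qi_target, config.quality_concentration,
        config.n_control, config.n_disease,
    )
    a0, b0, a1, b1 = _group_beta_params(delta, config.quality_concentration)
    q = np.concatenate([
        rng.beta(a0, b0, size=config.n_control),
        rng.beta(a1, b1, size=config.n_disease),
    ])
    if config.n_outliers > 0:
        q = _plant_outliers(q, config, rng)
    return np.clip(q, 0.0, 1.0)

def _plant_outliers(q: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Redraw selected samples' quality near ``outlier_p_low``.

    Outliers go preferentially into the disease group so that they confound
    the group contrast (the situation outlier removal is meant to fix).
    """
    n = config.n_control + config.n_disease
    disease_idx = np.arange(config.n_control, n)
    control_idx = np.arange(config.n_control)
    take = min(config.n_outliers, len(disease_idx))
    chosen = list(rng.choice(disease_idx, size=take, replace=False))
    if config.n_outliers > take:
        extra = min(config.n_outliers - take, len(control_idx))
        chosen += list(rng.choice(control_idx, size=extra, replace=False))
    mu, kappa = config.outlier_p_low, 150.0
    q = q.copy()
    q[np.asarray(chosen, dtype=int)] = rng.beta(mu * kappa, (1 - mu) * kappa, size=len(chosen))
    return q


def _assign_roles(config: SimConfig, rng: np.random.Generator,
                  gene_ids: list[str],
                  marker_low: Sequence[str] | None,
                  marker_high: Sequence[str] | None,
                  disease_genes: Sequence[str] | None):
    roles = pd.Series("null", index=gene_ids, name="role")
    if marker_low is None or marker_high is None:
        perm = rng.permutation(gene_ids)
        marker_low = list(perm[: config.n_low_markers])
        marker_high = list(perm[config.n_low_markers:
                                config.n_low_markers + config.n_high_markers])
        remaining = [g for g in perm[config.n_low_markers + config.n_high_markers:]]
    else:
        marker_low = list(marker_low)
        marker_high = list(marker_high)
        if len(marker_low) != config.n_low_markers or len(marker_high) != config.n_high_markers:
            raise ValueError("marker id lists must match configured marker counts")
        taken = set(marker_low) | set(marker_high)
        remaining = [g for g in gene_ids if g not in taken]
    if disease_genes is None:
        disease_genes = list(rng.choice(remaining, size=config.n_disease_genes,
                                        replace=False))
    roles.loc[marker_low] = "low_marker"
    roles.loc[marker_high] = "high_marker"
    roles.loc[list(disease_genes)] = "disease"

    beta_q = pd.Series(0.0, index=gene_ids, name="beta_quality")
    beta_q.loc[marker_low] = config.quality_effect
    beta_q.loc[marker_high] = -config.quality_effect
    beta_d = pd.Series(0.0, index=gene_ids, name="beta_disease")
    signs = rng.choice([-1.0, 1.0], size=len(disease_genes))
    magnitudes = config.disease_effect * rng.uniform(0.5, 1.5, size=len(disease_genes))
    beta_d.loc[list(disease_genes)] = signs * magnitudes
    return roles, beta_q, beta_d


def simulate_dataset(
    config: SimConfig,
    *,
    gene_ids: Sequence[str] | None = None,
    marker_low: Sequence[str] | None = None,
    marker_high: Sequence[str] | None = None,
    disease_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate one counts + metadata dataset.

    Returns ``(counts, samples, truth)``: a genes x samples integer
    DataFrame, a sample table (sample_id, group, p_low, pair_id) and the
    ground-truth record. Marker / disease gene identities may be pinned via
    the keyword lists (used by :func:`simulate_collection`).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_disease
    if gene_ids is None:
        gene_ids = [f"g{j:05d}" for j in range(config.n_genes)]
    else:
        gene_ids = [str(g) for g in gene_ids]
        if len(gene_ids) != config.n_genes:
            raise ValueError("gene_ids length must equal n_genes")

    q = _draw_quality(config, rng)
    g = np.concatenate([np.zeros(config.n_control, int), np.ones(config.n_disease, int)])
    roles, beta_q, beta_d = _assign_roles(config, rng, gene_ids,
                                          marker_low, marker_high, disease_genes)

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                             size=config.n_genes)
    shape, scale = config.dispersion_shape
    alpha = rng.gamma(shape, scale, size=config.n_genes) + 1e-4
    size_factors = rng.lognormal(0.0, config.libsize_sd, size=n)

    log2_mu = (beta_d.to_numpy()[:, None] * g[None, :]
               + beta_q.to_numpy()[:, None] * q[None, :])
    pair_ids: list | None = None
    if config.paired:
        # per-pair per-gene effect, shared by the two samples of a pair
        pair_effect = rng.normal(0.0, config.pair_sd,
                                 size=(config.n_genes, config.n_control))
        log2_mu += np.concatenate([pair_effect, pair_effect], axis=1)
        pair_ids = [f"p{i:03d}" for i in range(config.n_control)] * 2

    mu = baseline[:, None] * size_factors[None, :] * np.exp2(log2_mu)
    nb_n = 1.0 / alpha
    counts = rng.negative_binomial(nb_n[:, None], nb_n[:, None] / (nb_n[:, None] + mu))

    sample_ids = ([f"c{i:03d}" for i in range(config.n_control)]
                  + [f"d{i:03d}" for i in range(config.n_disease)])
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "group": g,
        "p_low": q,
        "pair_id": pair_ids if pair_ids is not None else pd.NA,
    })
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sample_ids)

    realized = qi.qi_pearson(samples).value
    truth = TruthRecord(
        genes=pd.DataFrame({"role": roles, "beta_quality": beta_q,
                            "beta_disease": beta_d}),
        sample_truth=pd.DataFrame({"sample_id": sample_ids, "quality": q,
                                   "size_factor": size_factors}),
        realized_qi=realized,
    )
    return counts_df, samples, truth


def simulate_collection(
    base: SimConfig,
    n_datasets: int,
    shared_marker_genes: Sequence[str],
) -> list[tuple[pd.DataFrame, pd.DataFrame, TruthRecord]]:
    """Simulate a collection of datasets sharing quality-marker identities.

    Emulates the marker-derivation setting: several independent low-QI
    datasets (one disease each) in which the *same* genes respond to sample
    quality, while disease-gene identities differ per dataset. The first
    ``base.n_low_markers`` entries of ``shared_marker_genes`` are planted as
    low-quality markers, the remaining ``base.n_high_markers`` as
    high-quality markers. Dataset seeds are ``base.seed + index``.
    """
    if n_datasets < 2:
        raise ValueError("a collection needs at least 2 datasets")
    n_markers = base.n_low_markers + base.n_high_markers
    if n_markers > 0 and len(shared_marker_genes) == 0:
        raise ValueError("shared_marker_genes is empty but marker counts are > 0")
    if len(shared_marker_genes) != n_markers:
        raise ValueError(
            f"shared_marker_genes has {len(shared_marker_genes)} entries; "
            f"config plants {n_markers} markers"
        )
    low = list(shared_marker_genes[: base.n_low_markers])
    high = list(shared_marker_genes[base.n_low_markers:])
    out = []
    for k in range(n_datasets):
        cfg = replace(base, seed=base.seed + k)
        out.append(simulate_dataset(cfg, marker_low=low, marker_high=high))
    return out


# ---------------------------------------------------------------------------
# ChIP-seq-like peak simulation

_TOY_CHROM = "chrT"


def simulate_peaks(
    config: SimConfig,
    n_bins: int,
    marker_bins: Sequence[int],
    bin_width: int = 500,
    presence_prob: float = 0.8,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, TruthRecord]:
    """Simulate per-sample peak calls on a toy chromosome.

    One candidate peak per 500-bp bin, present in each sample with
    probability ``presence_prob``; its enrichment is log-normal with a
    log2-linear quality effect in marker bins (the first
    ``config.n_low_markers`` entries of ``marker_bins`` respond positively
    to P_low, the rest negatively). Returns ``(peaks, samples, truth)``
    where ``peaks`` maps sample_id to a BED6+1-style DataFrame (chrom,
    start, end, name, score, strand, enrichment; 0-based half-open).
    """
    config.validate()
    marker_bins = [int(b) for b in marker_bins]
    if len(marker_bins) > n_bins:
        raise ValueError("more marker bins than bins")
    if marker_bins and (min(marker_bins) < 0 or max(marker_bins) >= n_bins):
        raise ValueError("marker bin index outside the toy chromosome")
    if len(marker_bins) != config.n_low_markers + config.n_high_markers:
        raise ValueError("marker_bins must match configured marker counts")
    chrom_len = n_bins * bin_width
    if chrom_len > 2**31 - 1:
        raise ValueError("toy chromosome coordinates overflow 32-bit range")

    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_disease
    q = _draw_quality(config, rng)
    g = np.concatenate([np.zeros(config.n_control, int), np.ones(config.n_disease, int)])

    beta = np.zeros(n_bins)
    low_bins = marker_bins[: config.n_low_markers]
    high_bins = marker_bins[config.n_low_markers:]
    beta[low_bins] = config.quality_effect
    beta[high_bins] = -config.quality_effect

    base_log2 = rng.normal(3.0, 0.5, size=n_bins)
    present = rng.random((n_bins, n)) < presence_prob
    noise = rng.normal(0.0, 0.3, size=(n_bins, n))
    enr = np.exp2(base_log2[:, None] + beta[:, None] * q[None, :] + noise)
    # peak geometry: one interval inside each bin
    starts = (np.arange(n_bins) * bin_width)[:, None] + rng.integers(0, bin_width // 4,
                                                                    size=(n_bins, n))
    lengths = rng.integers(bin_width // 2, bin_width - bin_width // 4, size=(n_bins, n))
    ends = np.minimum(starts + lengths, (np.arange(n_bins)[:, None] + 1) * bin_width)

    sample_ids = ([f"c{i:03d}" for i in range(config.n_control)]
                  + [f"d{i:03d}" for i in range(config.n_disease)])
    peaks: dict[str, pd.DataFrame] = {}
    for s_idx, sid in enumerate(sample_ids):
        keep = present[:, s_idx]
        peaks[sid] = pd.DataFrame({
            "chrom": _TOY_CHROM,
            "start": starts[keep, s_idx],
            "end": ends[keep, s_idx],
            "name": [f"{sid}_peak{b}" for b in np.flatnonzero(keep)],
            "score": 0,
            "strand": ".",
            "enrichment": enr[keep, s_idx],
        })

    samples = pd.DataFrame({"sample_id": sample_ids, "group": g, "p_low": q,
                            "pair_id": pd.NA})
    bin_role = np.full(n_bins, "null", dtype=object)
    bin_role[low_bins] = "low_marker"
    bin_role[high_bins] = "high_marker"
    bin_ids = [f"{_TOY_CHROM}:{i * bin_width}-{(i + 1) * bin_width}" for i in range(n_bins)]
    truth = TruthRecord(
        genes=pd.DataFrame(index=pd.Index([], name="gene_id"),
                           columns=["role", "beta_quality", "beta_disease"]),
        sample_truth=pd.DataFrame({"sample_id": sample_ids, "quality": q,
                                   "size_factor": 1.0}),
        realized_qi=qi.qi_pearson(samples).value,
        bins=pd.DataFrame({"bin": bin_ids, "role": bin_role, "beta_quality": beta}),
    )
    return peaks, samples, truth
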