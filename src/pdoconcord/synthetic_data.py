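"""Synthetic study-data generators with known ground truth.

The analyses in this package were designed around matched tumor/organoid
sequencing and viability-screen data that are not publicly deposited.  This
module generates every input kind the pipeline consumes, with the statistical
structure the analyses assume and with the generating truth returned
alongside, so each downstream stage can be validated by direct counting or
arithmetic on the truth object:

* paired allele-specific copy profiles with a controllable fraction of
  tumor events inherited by the organoid (segmental events on contiguous
  gene blocks);
* somatic variant sets with a controllable shared fraction; shared variants
  are clonal (allelic fraction centered at purity/2), private variants
  subclonal (centered at purity/6), both Beta-distributed;
* single-dose screen plates with vehicle, drug and staurosporine
  positive-control wells (positive control at 2% of baseline signal);
* dose-response tables from the unit-slope normalized-response curve
  Y = 100 / (1 + 10**(X - logIC50));
* replicate-level z-score vectors from the random-intercept model
  z = beta1 * x + u_sample + noise, and linear pathway-score/AUC couplings.

Every generator draws from a single ``numpy.random.default_rng(cfg.seed)``
created inside the call; a fixed config therefore reproduces byte-identical
output, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import CopyProfilePair, GeneCopyState, SomaticVariant
from .screen import (
    VEHICLE_LABELS,
    LayoutError,
    PlateScreen,
    WellMeasurement,
    default_vehicle_map,
)

__all__ = [
    "SimConfig",
    "InvalidConfigError",
    "gen_copy_profiles",
    "gen_variant_sets",
    "gen_screen_plate",
    "gen_dose_response",
    "gen_association_data",
    "gen_pathway_scores",
]

_BASES = np.array(["A", "C", "G", "T"])

# Beta concentration for allelic-fraction draws (a = c*m, b = c*(1-m)).
_AF_CONCENTRATION = 50.0


class InvalidConfigError(ValueError):
    pass


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidConfigError(msg)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all generators.

    Defaults mirror the observed cohort: shared deleterious SNVs ~74.7% of
    the union, high copy-event inheritance, >=3 drug replicates at Cmax with
    ~10% assay CV, and a 12-sample pharmacogenomic design with 3 replicates
    per sample.
    """

    seed: int = 0
    # copy profiles
    n_genes: int = 200
    shared_event_fraction: float = 0.8
    private_event_rate: float = 0.05
    # variants
    n_variants: int = 1000
    shared_variant_fraction: float = 0.747
    purity_tumor: float = 0.6
    purity_organoid: float = 0.9
    # screen plates
    n_drug_replicates: int = 3
    n_vehicle_replicates: int = 6
    effect_size: float = 0.6
    noise_cv: float = 0.1
    # dose-response
    logIC50_true: float = -6.0
    # association
    n_samples: int = 12
    n_reps_per_sample: int = 3
    beta1_true: float = -1.5
    random_intercept_sd: float = 0.5
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        _check(self.n_genes > 0, "n_genes must be positive")
        _check(self.n_variants > 0, "n_variants must be positive")
        for name in ("shared_event_fraction", "private_event_rate",
                     "shared_variant_fraction", "effect_size"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0,1], got {v}")
        for name in ("purity_tumor", "purity_organoid"):
            v = getattr(self, name)
            _check(0.0 < v <= 1.0, f"{name} must be in (0,1], got {v}")
        _check(self.n_drug_replicates >= 2, "n_drug_replicates must be >=2")
        _check(self.n_vehicle_replicates >= 2, "n_vehicle_replicates must be >=2")
        _check(self.noise_cv >= 0.0, "noise_cv must be >=0")
        _check(self.n_samples >= 2, "n_samples must be >=2")
        _check(self.n_reps_per_sample >= 1, "n_reps_per_sample must be >=1")
        _check(self.random_intercept_sd >= 0.0, "random_intercept_sd must be >=0")
        _check(self.residual_sd >= 0.0, "residual_sd must be >=0")


# ---------------------------------------------------------------------------
# copy profiles


def _apply_event(cn: np.ndarray, start: int, length: int, kind: str, delta: int):
    sl = slice(start, min(start + length, cn.shape[0]))
    if kind == "gain":
        cn[sl, 0] += delta
    else:  # loss of the minor allele (LOH when it reaches 0)
        cn[sl, 1] = np.maximum(cn[sl, 1] - delta, 0)


def gen_copy_profiles(
    cfg: SimConfig,
    sample_id: str = "SIM",
    n_events: Optional[int] = None,
    mean_block_len: float = 5.0,
) -> tuple[CopyProfilePair, pd.DataFrame]:
    """Paired tumor/organoid allele-specific copy profiles with event truth.

    The tumor starts diploid (cnA=1, cnB=1) at every gene and receives
    ``n_events`` (default n_genes // 20, min 1) gain/loss events on contiguous
    gene blocks with geometric block lengths.  The organoid inherits each
    tumor event independently with probability ``shared_event_fraction`` and
    acquires Poisson(private_event_rate * n_events) private events of its own.
    Returns the pair and a truth table of events (block, kind, carrier).
    """
    rng = np.random.default_rng(cfg.seed)
    if n_events is None:
        n_events = max(1, cfg.n_genes // 20)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tumor_cn = np.ones((cfg.n_genes, 2), dtype=float)
    organoid_cn = np.ones((cfg.n_genes, 2), dtype=float)

    events = []
    p_geom = min(1.0, 1.0 / mean_block_len)
    for _ in range(n_events):
        start = int(rng.integers(0, cfg.n_genes))
        length = int(rng.geometric(p_geom))
        kind = "gain" if rng.random() < 0.5 else "loss"
        delta = int(rng.integers(1, 3)) if kind == "gain" else 1
        inherited = bool(rng.random() < cfg.shared_event_fraction)
        _apply_event(tumor_cn, start, length, kind, delta)
        if inherited:
            _apply_event(organoid_cn, start, length, kind, delta)
        events.append(dict(start=start, length=length, kind=kind, delta=delta,
                           carrier="shared" if inherited else "tumor_private"))
    n_private = int(rng.poisson(cfg.private_event_rate * n_events))
    for _ in range(n_private):
        start = int(rng.integers(0, cfg.n_genes))
        length = int(rng.geometric(p_geom))
        kind = "gain" if rng.random() < 0.5 else "loss"
        delta = int(rng.integers(1, 3)) if kind == "gain" else 1
        _apply_event(organoid_cn, start, length, kind, delta)
        events.append(dict(start=start, length=length, kind=kind, delta=delta,
                           carrier="organoid_private"))

    def states(cn: np.ndarray) -> tuple[GeneCopyState, ...]:
        # keep the (major, minor) ordering invariant cnA >= cnB
        hi = np.maximum(cn[:, 0], cn[:, 1])
        lo = np.minimum(cn[:, 0], cn[:, 1])
        return tuple(
            GeneCopyState(g, float(a), float(b)) for g, a, b in zip(genes, hi, lo)
        )

    pair = CopyProfilePair(
        sample_id=sample_id, tumor=states(tumor_cn), organoid=states(organoid_cn)
    )
    return pair, pd.DataFrame(events)


# ---------------------------------------------------------------------------
# variants


def _beta_af(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    a = _AF_CONCENTRATION * mean
    b = _AF_CONCENTRATION * (1.0 - mean)
    return rng.beta(a, b, size=size)


def gen_variant_sets(
    cfg: SimConfig, p_deleterious: float = 0.7
) -> tuple[list[SomaticVariant], list[SomaticVariant], pd.DataFrame]:
    """Tumor and organoid somatic variant lists with shared/private truth.

    Each of ``n_variants`` loci is shared with probability
    ``shared_variant_fraction``; otherwise it is tumor-private or
    organoid-private with equal probability.  Shared variants are clonal —
    allelic fraction Beta-distributed around purity/2 in each sample
    separately — while private variants are subclonal, centered at purity/6
    in their carrier.  Returns (tumor, organoid, truth) with one truth row per
    locus (key columns plus label).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_variants
    u = rng.random(n)
    labels = np.where(
        u < cfg.shared_variant_fraction,
        "shared",
        np.where(rng.random(n) < 0.5, "tumor_private", "organoid_private"),
    )
    chrom = rng.integers(1, 23, size=n).astype(str)
    pos = rng.integers(1, 10**8, size=n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    deleterious = rng.random(n) < p_deleterious

    af_t_clonal = _beta_af(rng, cfg.purity_tumor / 2.0, n)
    af_o_clonal = _beta_af(rng, cfg.purity_organoid / 2.0, n)
    af_t_sub = _beta_af(rng, cfg.purity_tumor / 6.0, n)
    af_o_sub = _beta_af(rng, cfg.purity_organoid / 6.0, n)

    tumor, organoid, rows = [], [], []
    seen = set()
    for i in range(n):
        key = (chrom[i], int(pos[i]), _BASES[ref_idx[i]], _BASES[alt_idx[i]])
        if key in seen:  # vanishingly rare at genome scale; keep keys unique
            continue
        seen.add(key)
        kw = dict(chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                  deleterious=bool(deleterious[i]))
        if labels[i] == "shared":
            tumor.append(SomaticVariant(vaf=float(af_t_clonal[i]), **kw))
            organoid.append(SomaticVariant(vaf=float(af_o_clonal[i]), **kw))
        elif labels[i] == "tumor_private":
            tumor.append(SomaticVariant(vaf=float(af_t_sub[i]), **kw))
        else:
            organoid.append(SomaticVariant(vaf=float(af_o_sub[i]), **kw))
        rows.append(dict(chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                         label=labels[i], deleterious=bool(deleterious[i])))
    return tumor, organoid, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screen plates


def gen_screen_plate(
    cfg: SimConfig,
    drug_effects: Mapping[str, float],
    vehicle_map: Optional[Mapping[str, str]] = None,
    specimen: str = "SIM",
    baseline: float = 1000.0,
    positive_control_fraction: float = 0.02,
) -> PlateScreen:
    """A simulated single-dose screen plate.

    Vehicle wells fluctuate around ``baseline`` with coefficient of variation
    ``noise_cv``; each drug's wells around baseline * (1 - effect); the
    staurosporine positive control around ``positive_control_fraction`` of
    baseline (near-complete kill).  Signals are truncated at zero, as a
    luminescence readout would be.
    """
    rng = np.random.default_rng(cfg.seed)
    drugs = list(drug_effects)
    if vehicle_map is None:
        vehicle_map = default_vehicle_map(drugs)
    vehicle_map = dict(vehicle_map)
    for d in drugs:
        if d not in vehicle_map:
            raise LayoutError(f"no vehicle label for drug {d!r}")
        if vehicle_map[d] not in VEHICLE_LABELS:
            raise LayoutError(
                f"vehicle for {d!r} must be one of {VEHICLE_LABELS}, "
                f"got {vehicle_map[d]!r}"
            )

    def noisy(mean: float, size: int) -> np.ndarray:
        draws = mean * (1.0 + cfg.noise_cv * rng.standard_normal(size))
        return np.maximum(draws, 0.0)

    wells: list[WellMeasurement] = []
    k = 0
    for label in sorted({vehicle_map[d] for d in drugs}) or ["DMSO"]:
        for sig in noisy(baseline, cfg.n_vehicle_replicates):
            wells.append(WellMeasurement(f"W{k:03d}", "vehicle", float(sig),
                                         vehicle=label))
            k += 1
    for d in drugs:
        effect = drug_effects[d]
        if not (0.0 <= effect <= 1.0):
            raise InvalidConfigError(f"effect for {d!r} must be in [0,1]")
        for sig in noisy(baseline * (1.0 - effect), cfg.n_drug_replicates):
            wells.append(WellMeasurement(f"W{k:03d}", "drug", float(sig), drug=d))
            k += 1
    for sig in noisy(baseline * positive_control_fraction, cfg.n_vehicle_replicates):
        wells.append(WellMeasurement(f"W{k:03d}", "positive_control", float(sig)))
        k += 1
    return PlateScreen(specimen=specimen, wells=tuple(wells),
                       vehicle_map=vehicle_map)


# ---------------------------------------------------------------------------
# dose-response


def gen_dose_response(
    cfg: SimConfig,
    concentrations: Sequence[float],
    n_replicates: int = 3,
    drug: str = "drug",
) -> tuple[pd.DataFrame, float]:
    """Replicated normalized-response measurements along a dilution series.

    At each concentration the noiseless response is
    Y = 100 / (1 + 10**(X - logIC50_true)) with X = log10(concentration);
    multiplicative Gaussian noise with CV ``noise_cv`` is added per replicate.
    Returns (table, true logIC50); the table has columns drug, concentration,
    replicate, viability.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    _check(conc.size > 0, "concentration list must be non-empty")
    _check(np.unique(conc).size >= 4, "need >=4 distinct concentrations")
    _check(bool(np.all(conc > 0)), "concentrations must be > 0 (molar)")
    _check(n_replicates >= 3, "need >=3 replicates per concentration")
    rng = np.random.default_rng(cfg.seed)
    x = np.log10(conc)
    y0 = 100.0 / (1.0 + 10.0 ** (x - cfg.logIC50_true))
    rows = []
    for c, y in zip(conc, y0):
        for r in range(n_replicates):
            noise = cfg.noise_cv * rng.standard_normal() if cfg.noise_cv else 0.0
            rows.append(dict(drug=drug, concentration=c, replicate=r,
                             viability=float(y * (1.0 + noise))))
    return pd.DataFrame(rows), cfg.logIC50_true


# ---------------------------------------------------------------------------
# association designs


def gen_association_data(
    cfg: SimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Replicate-level z-scores from the random-intercept generating model.

    Samples are split as evenly as possible into mutated (x=1) and wild-type
    (x=0); each sample draws a random intercept u ~ N(0, random_intercept_sd^2)
    and each replicate z = beta1_true * x + u + N(0, residual_sd^2).
    Returns (z, x per replicate, sample ids per replicate, truth dict).
    """
    if cfg.n_samples < 4:
        import warnings

        warnings.warn("fewer than 4 samples: association is weakly identified",
                      stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    n_mut = cfg.n_samples // 2
    x_sample = np.array([1] * n_mut + [0] * (cfg.n_samples - n_mut), dtype=float)
    u = rng.normal(0.0, cfg.random_intercept_sd, size=cfg.n_samples)
    sample_ids = np.repeat(
        np.array([f"S{i:02d}" for i in range(cfg.n_samples)]), cfg.n_reps_per_sample
    )
    x = np.repeat(x_sample, cfg.n_reps_per_sample)
    u_rep = np.repeat(u, cfg.n_reps_per_sample)
    eps = rng.normal(0.0, cfg.residual_sd, size=x.size)
    z = cfg.beta1_true * x + u_rep + eps
    truth = dict(beta1=cfg.beta1_true, random_intercepts=u, x_sample=x_sample)
    return z, x, sample_ids, truth


def gen_pathway_scores(
    auc: Sequence[float], slope: float, noise_sd: float, seed: int
) -> tuple[np.ndarray, float]:
    """Per-sample pathway scores linearly coupled to drug AUC.

    score = slope * auc + N(0, noise_sd^2); returns (scores, true slope).
    """
    auc = np.asarray(auc, dtype=float)
    if np.any((auc < 0) | (auc > 1)):
        raise InvalidConfigError("auc values must be in [0,1]")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=auc.size) if noise_sd else np.zeros(auc.size)
    return slope * auc + noise, slope
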