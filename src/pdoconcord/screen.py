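"""Single-dose (Cmax) viability-screen statistics and sensitivity calling.

Each drug is screened at its clinical Cmax in >=3 technical replicates per
specimen, alongside vehicle wells (DMSO, or H2O for the water-soluble drugs
cisplatin, carboplatin and 5-FU) and staurosporine positive-control wells.

Per drug the pipeline computes:

* replicate z-scores against the matched vehicle: z = (X_s - X_v) / SD_v,
  where X_v and SD_v are the mean and sample SD of the vehicle replicates;
* fold-change of raw signal relative to the vehicle mean (and 1 - FC, the
  fractional viability reduction);
* a Dunnett-adjusted p-value from a one-way ANOVA comparing every drug group
  mapped to the same vehicle against that vehicle (many-to-one family);
* the three-criterion sensitivity call:
  z_mean <= -1.5  AND  p_adj < 0.05  AND  1 - FC > 0.5.

Plate quality is summarised by the Z-factor
Z' = 1 - 3 (SD_pos + SD_neg) / |mean_pos - mean_neg|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WellMeasurement",
    "PlateScreen",
    "DrugCallResult",
    "normalize_zscores",
    "z_factor",
    "fold_change",
    "dunnett_adjusted_p",
    "call_sensitivity",
    "screen_report",
    "LayoutError",
    "DegenerateVehicleError",
]

VEHICLE_LABELS = ("DMSO", "H2O")

# Drugs the assay dissolves in water; everything else uses DMSO.
DEFAULT_H2O_DRUGS = ("cisplatin", "carboplatin", "5-FU")

# Internal seed for the Dunnett multivariate-t integration: adjusted p-values
# must be reproducible across calls, independent of any user seed.
_DUNNETT_SEED = 20240917


class LayoutError(ValueError):
    """Plate layout is missing wells a computation needs."""


class DegenerateVehicleError(ValueError):
    """Vehicle wells carry no usable signal (zero SD or zero mean)."""


@dataclass(frozen=True)
class WellMeasurement:
    well: str
    role: Literal["drug", "vehicle", "positive_control"]
    raw_signal: float
    drug: Optional[str] = None  # role == "drug"
    vehicle: Optional[str] = None  # vehicle label for vehicle wells

    def __post_init__(self) -> None:
        if self.raw_signal < 0:
            raise ValueError(f"raw_signal must be >= 0, got {self.raw_signal}")
        if self.role == "drug" and not self.drug:
            raise ValueError(f"well {self.well}: drug wells need a drug name")
        if self.role == "vehicle" and self.vehicle not in VEHICLE_LABELS:
            raise ValueError(
                f"well {self.well}: vehicle label must be one of {VEHICLE_LABELS}"
            )


@dataclass(frozen=True)
class PlateScreen:
    """One specimen's screen: wells plus the drug -> vehicle-label map."""

    specimen: str
    wells: tuple[WellMeasurement, ...]
    vehicle_map: dict[str, str] = field(default_factory=dict)

    def drugs(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            if w.role == "drug" and w.drug not in seen:
                seen[w.drug] = None
        return list(seen)

    def drug_signals(self, drug: str) -> np.ndarray:
        x = np.array(
            [w.raw_signal for w in self.wells if w.role == "drug" and w.drug == drug]
        )
        if x.size == 0:
            raise LayoutError(f"no wells for drug {drug!r}")
        return x

    def vehicle_signals(self, label: Optional[str] = None) -> np.ndarray:
        x = np.array(
            [
                w.raw_signal
                for w in self.wells
                if w.role == "vehicle" and (label is None or w.vehicle == label)
            ]
        )
        if x.size == 0:
            raise LayoutError(f"no vehicle wells with label {label!r}")
        return x

    def positive_signals(self) -> np.ndarray:
        return np.array(
            [w.raw_signal for w in self.wells if w.role == "positive_control"]
        )

    def vehicle_for(self, drug: str) -> str:
        try:
            return self.vehicle_map[drug]
        except KeyError:
            raise LayoutError(f"no vehicle mapping for drug {drug!r}") from None


@dataclass(frozen=True)
class DrugCallResult:
    drug: str
    z_scores: tuple[float, ...]
    z_mean: float
    fold_change: float
    one_minus_fc: float
    p_adj: float
    sensitive: bool
    z_factor: float


def default_vehicle_map(drugs: Sequence[str]) -> dict[str, str]:
    """H2O for cisplatin/carboplatin/5-FU (case-insensitive), DMSO otherwise."""
    h2o = {d.lower() for d in DEFAULT_H2O_DRUGS}
    return {d: ("H2O" if d.lower() in h2o else "DMSO") for d in drugs}


def _vehicle_stats(plate: PlateScreen, drug: str) -> tuple[np.ndarray, float, float]:
    veh = plate.vehicle_signals(plate.vehicle_for(drug))
    if veh.size < 2:
        raise LayoutError(f"vehicle for {drug!r} needs >=2 wells, has {veh.size}")
    mean = float(veh.mean())
    sd = float(veh.std(ddof=1))
    return veh, mean, sd


def normalize_zscores(plate: PlateScreen, drug: str) -> np.ndarray:
    """Per-replicate z-scores of a drug against its matched vehicle."""
    _, v_mean, v_sd = _vehicle_stats(plate, drug)
    if v_sd == 0:
        raise DegenerateVehicleError(
            f"vehicle SD is zero for drug {drug!r}; z-score undefined"
        )
    return (plate.drug_signals(drug) - v_mean) / v_sd


def z_factor(plate: PlateScreen, vehicle: Optional[str] = None) -> float:
    """Assay-window quality: Z' = 1 - 3(SD_pos + SD_neg)/|mean_pos - mean_neg|.

    Positive control is staurosporine (near-complete kill); the negative
    control is the named vehicle, or all vehicle wells pooled when ``vehicle``
    is None.  The absolute mean difference is used so that Z' keeps its
    standard semantics (Z' <= 1, larger is better) regardless of which control
    reads higher.
    """
    pos = plate.positive_signals()
    neg = plate.vehicle_signals(vehicle)
    if pos.size < 2 or neg.size < 2:
        raise LayoutError("Z-factor needs >=2 positive and >=2 vehicle wells")
    sep = abs(float(pos.mean()) - float(neg.mean()))
    if sep == 0:
        raise DegenerateVehicleError("Z-factor undefined: control means are equal")
    return 1.0 - 3.0 * (float(pos.std(ddof=1)) + float(neg.std(ddof=1))) / sep


def fold_change(plate: PlateScreen, drug: str) -> tuple[float, float]:
    """(FC, 1-FC): drug raw-signal mean over matched-vehicle raw-signal mean."""
    _, v_mean, _ = _vehicle_stats(plate, drug)
    if v_mean == 0:
        raise DegenerateVehicleError(f"vehicle mean is zero for drug {drug!r}")
    fc = float(plate.drug_signals(drug).mean()) / v_mean
    return fc, 1.0 - fc


def dunnett_adjusted_p(plate: PlateScreen, vehicle: str) -> dict[str, float]:
    """Dunnett many-to-one adjusted p-values for all drugs on one vehicle.

    Each drug group mapped to ``vehicle`` is compared (two-sided) against that
    vehicle's wells inside a one-way ANOVA on raw signals; adjusted p-values
    come from the Dunnett multivariate-t distribution.  Drugs on H2O and on
    DMSO form separate families.  A single-drug family reduces exactly to the
    pooled-variance two-sample t-test.
    """
    drugs = [d for d in plate.drugs() if plate.vehicle_for(d) == vehicle]
    if not drugs:
        return {}
    control = plate.vehicle_signals(vehicle)
    if control.size < 2:
        raise LayoutError(f"vehicle {vehicle!r} needs >=2 wells")
    groups = []
    for d in drugs:
        g = plate.drug_signals(d)
        if g.size < 2:
            raise LayoutError(f"drug {d!r} needs >=2 replicates for the ANOVA")
        groups.append(g)
    if len(groups) == 1:
        # Dunnett with one comparison is the two-sample pooled-variance t-test.
        p = float(stats.ttest_ind(groups[0], control, equal_var=True).pvalue)
        return {drugs[0]: p}
    res = stats.dunnett(
        *groups, control=control, alternative="two-sided",
        rng=np.random.default_rng(_DUNNETT_SEED),
    )
    return {d: float(min(1.0, p)) for d, p in zip(drugs, res.pvalue)}


def call_sensitivity(
    z_mean: float,
    p_adj: float,
    fc: float,
    z_cut: float = -1.5,
    p_cut: float = 0.05,
    one_minus_fc_cut: float = 0.5,
) -> bool:
    """True iff z_mean <= z_cut AND p_adj < p_cut AND 1-FC > one_minus_fc_cut."""
    for v in (z_mean, p_adj, fc):
        if not np.isfinite(v):
            raise ValueError("sensitivity call requires finite inputs")
    return (z_mean <= z_cut) and (p_adj < p_cut) and ((1.0 - fc) > one_minus_fc_cut)


def screen_report(
    plate: PlateScreen,
    z_cut: float = -1.5,
    p_cut: float = 0.05,
    one_minus_fc_cut: float = 0.5,
) -> list[DrugCallResult]:
    """Full per-drug analysis of one specimen's plate.

    Runs z-score normalization, fold-change, per-vehicle-family Dunnett
    adjustment and the three-criterion sensitivity call for every drug;
    attaches the plate-level Z-factor to each row.
    """
    drugs = plate.drugs()
    if not drugs:
        return []
    try:
        zf = z_factor(plate)
    except (LayoutError, DegenerateVehicleError):
        zf = float("nan")
    p_adj: dict[str, float] = {}
    for vehicle in sorted({plate.vehicle_for(d) for d in drugs}):
        p_adj.update(dunnett_adjusted_p(plate, vehicle))
    out = []
    for d in drugs:
        try:
            z = normalize_zscores(plate, d)
            fc, one_minus = fold_change(plate, d)
        except (LayoutError, DegenerateVehicleError) as e:
            raise type(e)(f"drug {d!r}: {e}") from e
        z_mean = float(z.mean())
        sensitive = call_sensitivity(
            z_mean, p_adj[d], fc, z_cut, p_cut, one_minus_fc_cut
        )
        out.append(
            DrugCallResult(
                drug=d,
                z_scores=tuple(float(v) for v in z),
                z_mean=z_mean,
                fold_change=fc,
                one_minus_fc=one_minus,
                p_adj=p_adj[d],
                sensitive=sensitive,
                z_factor=zf,
            )
        )
    return out
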