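"""Readers, writers, run configuration and the pipeline driver.

Interchange dialects: UTF-8 TSV/CSV with a mandatory header row, '.' decimal,
no index column.  Rows beginning with '#' are metadata comments (the writers
stamp every output with the run's config hash and seed) and are skipped on
read.  VCF is read-only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import dose_response as dr
from .concordance import (
    CopyProfilePair,
    GeneCopyState,
    PairingError,
    SomaticVariant,
    cnv_similarity,
    compare_af,
    correct_allelic_fraction,
    filter_confident_variants,
    partition_variants,
)
from .screen import PlateScreen, WellMeasurement, screen_report
from .synthetic_data import (
    SimConfig,
    gen_association_data,
    gen_copy_profiles,
    gen_dose_response,
    gen_pathway_scores,
    gen_screen_plate,
    gen_variant_sets,
)

__all__ = [
    "RunConfig",
    "read_variants",
    "write_variants",
    "read_copy_profiles",
    "write_copy_profile",
    "read_plate",
    "write_plate",
    "read_dose_table",
    "write_dose_table",
    "run_pipeline",
    "PlanError",
]

log = logging.getLogger("pdoconcord")

STAGES = ("simulate", "concordance", "screen", "dose", "associate")


class PlanError(ValueError):
    """The requested stage set cannot be executed with the given inputs."""


class SchemaError(ValueError):
    """An input file does not match its expected schema."""


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the published cutoffs."""

    seed: int = 0
    out_dir: str = "pdoconcord_out"
    # analysis thresholds
    z_cut: float = -1.5
    p_cut: float = 0.05
    one_minus_fc_cut: float = 0.5
    vaf_min: float = 0.05
    auc_cut: float = 0.5
    # optional explicit inputs (filled by the simulate stage otherwise)
    tumor_cn: Optional[str] = None
    organoid_cn: Optional[str] = None
    tumor_variants: Optional[str] = None
    organoid_variants: Optional[str] = None
    purity: dict = field(default_factory=dict)  # sample -> {"tumor":p,"organoid":p}
    plate: Optional[str] = None
    dose: Optional[str] = None
    zscores: Optional[str] = None
    mutations: Optional[str] = None
    vehicle_map: dict = field(default_factory=dict)
    log_level: str = "INFO"
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        """Digest of the analytic configuration (seed, thresholds, vehicle
        map, simulation parameters) — file locations do not change results,
        so they are excluded and two runs of the same analysis hash equal."""
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k in ("seed", "z_cut", "p_cut", "one_minus_fc_cut", "vaf_min",
                     "auc_cut", "vehicle_map", "sim")
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers / writers


def _stamp(cfg: Optional[RunConfig]) -> str:
    if cfg is None:
        return ""
    return f"# config_hash={cfg.hash()} seed={cfg.seed}\n"


def _write_frame(df: pd.DataFrame, path: str | Path, sep: str,
                 cfg: Optional[RunConfig]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, sep=sep, index=False, float_format="%.12g",
                  lineterminator="\n")


def _read_frame(path: str | Path, sep: str, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_variants(variants: Sequence[SomaticVariant], path: str | Path,
                   cfg: Optional[RunConfig] = None) -> None:
    df = pd.DataFrame(
        [
            dict(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, vaf=v.vaf,
                 deleterious=v.deleterious)
            for v in variants
        ]
    )
    _write_frame(df, Path(path), "\t", cfg)


def _variants_from_frame(df: pd.DataFrame, path) -> list[SomaticVariant]:
    out = []
    for idx, row in df.iterrows():
        try:
            vaf = float(row["vaf"])
            pos = int(row["pos"])
        except (TypeError, ValueError) as e:
            # +2 for the header line, 1-based file lines
            raise SchemaError(f"{path}: malformed row at line {idx + 2}: {e}") from e
        out.append(
            SomaticVariant(chrom=str(row["chrom"]), pos=pos, ref=str(row["ref"]),
                           alt=str(row["alt"]), vaf=vaf,
                           deleterious=bool(row.get("deleterious", False)))
        )
    return out


def read_variants(path: str | Path, format: str = "tsv",
                  af_field: str = "AF") -> list[SomaticVariant]:
    """Read somatic variants from a MAF-like TSV or a VCF (1-based positions)."""
    if format == "tsv":
        df = _read_frame(path, "\t", {"chrom", "pos", "ref", "alt", "vaf"})
        return _variants_from_frame(df, path)
    if format == "vcf":
        try:
            from cyvcf2 import VCF
        except ImportError as e:  # pragma: no cover - cyvcf2 is an extra
            raise ImportError("VCF reading requires the cyvcf2 extra") from e
        out = []
        for rec in VCF(str(path)):
            af = rec.INFO.get(af_field)
            if af is None:
                try:
                    af = float(np.ravel(rec.format(af_field))[0])
                except (TypeError, KeyError):
                    raise SchemaError(
                        f"{path}: no {af_field!r} in INFO or FORMAT at "
                        f"{rec.CHROM}:{rec.POS}"
                    ) from None
            for alt in rec.ALT:
                out.append(SomaticVariant(chrom=rec.CHROM, pos=rec.POS,
                                          ref=rec.REF, alt=alt, vaf=float(af)))
        return out
    raise SchemaError(f"unknown variant format {format!r}")


def write_copy_profile(states: Iterable[GeneCopyState], path: str | Path,
                       cfg: Optional[RunConfig] = None) -> None:
    df = pd.DataFrame([dict(gene=s.gene, cnA=s.cnA, cnB=s.cnB) for s in states])
    _write_frame(df, Path(path), "\t", cfg)


def read_copy_profiles(tumor_path: str | Path, organoid_path: str | Path,
                       sample_id: str = "sample") -> CopyProfilePair:
    """Inner-join tumor and organoid per-gene copy tables into an aligned pair."""
    t = _read_frame(tumor_path, "\t", {"gene", "cnA", "cnB"})
    o = _read_frame(organoid_path, "\t", {"gene", "cnA", "cnB"})
    merged = t.merge(o, on="gene", how="inner", suffixes=("_t", "_o"))
    if merged.empty:
        raise PairingError("tumor and organoid profiles share no genes")
    dropped = (set(t["gene"]) | set(o["gene"])) - set(merged["gene"])
    if dropped:
        log.warning("%d genes present in only one profile were dropped",
                    len(dropped))
    return CopyProfilePair(
        sample_id=sample_id,
        tumor=tuple(GeneCopyState(g, a, b) for g, a, b in
                    zip(merged["gene"], merged["cnA_t"], merged["cnB_t"])),
        organoid=tuple(GeneCopyState(g, a, b) for g, a, b in
                       zip(merged["gene"], merged["cnA_o"], merged["cnB_o"])),
    )


def write_plate(plate: PlateScreen, path: str | Path,
                cfg: Optional[RunConfig] = None) -> None:
    rows = []
    for w in plate.wells:
        vehicle = w.vehicle if w.role == "vehicle" else (
            plate.vehicle_map.get(w.drug) if w.role == "drug" else None
        )
        rows.append(dict(specimen=plate.specimen, well=w.well, role=w.role,
                         drug=w.drug or "", vehicle=vehicle or "",
                         signal=w.raw_signal))
    _write_frame(pd.DataFrame(rows), Path(path), ",", cfg)


def read_plate(path: str | Path) -> PlateScreen:
    df = _read_frame(path, ",", {"specimen", "well", "role", "drug", "vehicle",
                                 "signal"})
    specimens = df["specimen"].unique()
    if len(specimens) != 1:
        raise SchemaError(f"{path}: expected one specimen, got {list(specimens)}")
    wells, vehicle_map = [], {}
    for _, r in df.iterrows():
        role = str(r["role"])
        drug = str(r["drug"]) if isinstance(r["drug"], str) and r["drug"] else None
        vehicle = (str(r["vehicle"])
                   if isinstance(r["vehicle"], str) and r["vehicle"] else None)
        wells.append(WellMeasurement(
            well=str(r["well"]), role=role, raw_signal=float(r["signal"]),
            drug=drug, vehicle=vehicle if role == "vehicle" else None,
        ))
        if role == "drug" and drug and vehicle:
            vehicle_map[drug] = vehicle
    return PlateScreen(specimen=str(specimens[0]), wells=tuple(wells),
                       vehicle_map=vehicle_map)


def write_dose_table(df: pd.DataFrame, path: str | Path,
                     cfg: Optional[RunConfig] = None) -> None:
    out = df.rename(columns={"concentration": "concentration_M"})
    _write_frame(out, Path(path), ",", cfg)


def read_dose_table(path: str | Path) -> pd.DataFrame:
    df = _read_frame(path, ",", {"drug", "concentration_M", "replicate",
                                 "viability"})
    return df.rename(columns={"concentration_M": "concentration"})


# ---------------------------------------------------------------------------
# pipeline driver


def _plan(cfg: RunConfig, stages: Sequence[str]) -> None:
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PlanError(f"unknown stages: {sorted(unknown)}")
    sim = "simulate" in stages
    need = {
        "concordance": [cfg.tumor_cn, cfg.organoid_cn, cfg.tumor_variants,
                        cfg.organoid_variants],
        "screen": [cfg.plate],
        "dose": [cfg.dose],
        "associate": [cfg.zscores, cfg.mutations],
    }
    for stage, inputs in need.items():
        if stage in stages and not sim and any(p is None for p in inputs):
            raise PlanError(
                f"stage {stage!r} requested without its inputs and without "
                f"'simulate'"
            )


def run_pipeline(cfg: RunConfig, stages: Sequence[str]) -> dict:
    """Execute the requested stages in dependency order.

    ``simulate`` writes every synthetic input kind into the output directory
    and wires later stages to consume them.  Returns the run manifest (also
    written to ``manifest.json``), which records the config hash, seed and all
    artifacts.
    """
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    _plan(cfg, stages)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.hash(), "seed": cfg.seed,
                      "stages": list(stages), "artifacts": {}}
    art = manifest["artifacts"]

    sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)

    if "simulate" in stages:
        log.info("simulate: writing synthetic inputs to %s", out)
        pair, events = gen_copy_profiles(sim_cfg)
        cfg.tumor_cn = str(out / "tumor_cn.tsv")
        cfg.organoid_cn = str(out / "organoid_cn.tsv")
        write_copy_profile(pair.tumor, cfg.tumor_cn, cfg)
        write_copy_profile(pair.organoid, cfg.organoid_cn, cfg)
        _write_frame(events, out / "cn_event_truth.tsv", "\t", cfg)

        tum, org, truth = gen_variant_sets(sim_cfg)
        cfg.tumor_variants = str(out / "tumor_variants.tsv")
        cfg.organoid_variants = str(out / "organoid_variants.tsv")
        write_variants(tum, cfg.tumor_variants, cfg)
        write_variants(org, cfg.organoid_variants, cfg)
        _write_frame(truth, out / "variant_truth.tsv", "\t", cfg)
        cfg.purity = {"SIM": {"tumor": sim_cfg.purity_tumor,
                              "organoid": sim_cfg.purity_organoid}}
        _write_frame(
            pd.DataFrame([dict(sample="SIM", tumor=sim_cfg.purity_tumor,
                               organoid=sim_cfg.purity_organoid)]),
            out / "purity.tsv", "\t", cfg,
        )

        effects = {"cisplatin": sim_cfg.effect_size, "gemcitabine": 0.0,
                   "docetaxel": 0.0, "erdafitinib": 0.0}
        plate = gen_screen_plate(sim_cfg, effects,
                                 vehicle_map=cfg.vehicle_map or None)
        cfg.plate = str(out / "plate.csv")
        write_plate(plate, cfg.plate, cfg)

        conc = np.logspace(sim_cfg.logIC50_true - 3, sim_cfg.logIC50_true + 3, 7)
        dose_df, _ = gen_dose_response(sim_cfg, conc)
        cfg.dose = str(out / "dose.csv")
        write_dose_table(dose_df, cfg.dose, cfg)

        z, x, sample_ids, truth_a = gen_association_data(sim_cfg)
        zdf = pd.DataFrame({"sample": sample_ids, "drug": "cisplatin",
                            "replicate": np.tile(
                                np.arange(sim_cfg.n_reps_per_sample),
                                sim_cfg.n_samples),
                            "z": z})
        cfg.zscores = str(out / "zscores.tsv")
        _write_frame(zdf, cfg.zscores, "\t", cfg)
        mut = pd.DataFrame(
            {"sample": [f"S{i:02d}" for i in range(sim_cfg.n_samples)],
             "TP53": truth_a["x_sample"].astype(int)}
        )
        cfg.mutations = str(out / "mutations.tsv")
        _write_frame(mut, cfg.mutations, "\t", cfg)
        art["simulate"] = sorted(p.name for p in out.glob("*.tsv"))

    if "concordance" in stages:
        log.info("concordance: CNV similarity and variant partition")
        pair = read_copy_profiles(cfg.tumor_cn, cfg.organoid_cn, "SIM")
        sim_res = cnv_similarity(pair)
        per_gene = pd.DataFrame({"gene": sim_res.genes, "d": sim_res.per_gene_d,
                                 "s": sim_res.per_gene_s})
        _write_frame(per_gene, out / "cnv_similarity.tsv", "\t", cfg)

        tum = filter_confident_variants(
            read_variants(cfg.tumor_variants), cfg.vaf_min)
        org = filter_confident_variants(
            read_variants(cfg.organoid_variants), cfg.vaf_min)
        part = partition_variants(tum, org, deleterious_only=True)
        purity = cfg.purity.get("SIM", {"tumor": 1.0, "organoid": 1.0})
        shared_af = [correct_allelic_fraction(v, purity["tumor"])
                     for v in part.shared]
        private_af = (
            [correct_allelic_fraction(v, purity["tumor"])
             for v in part.tumor_private]
            + [correct_allelic_fraction(v, purity["organoid"])
               for v in part.organoid_private]
        )
        stat, p = compare_af(shared_af, private_af) if shared_af and private_af \
            else (float("nan"), float("nan"))
        summary = {
            "config_hash": cfg.hash(), "seed": cfg.seed,
            "summary_similarity": sim_res.summary_s,
            "degenerate_normalization": sim_res.degenerate,
            "proportions": dict(zip(("shared", "tumor_private",
                                     "organoid_private"), part.proportions)),
            "af_wilcoxon": {"U": stat, "p": p},
        }
        (out / "concordance_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        art["concordance"] = ["cnv_similarity.tsv", "concordance_summary.json"]

    if "screen" in stages:
        log.info("screen: z-scores, Dunnett, sensitivity calls")
        plate = read_plate(cfg.plate)
        report = screen_report(plate, cfg.z_cut, cfg.p_cut, cfg.one_minus_fc_cut)
        rep_df = pd.DataFrame(
            [dict(specimen=plate.specimen, drug=r.drug, z_mean=r.z_mean,
                  fold_change=r.fold_change, one_minus_fc=r.one_minus_fc,
                  p_adj=r.p_adj, sensitive=r.sensitive, z_factor=r.z_factor)
             for r in report]
        )
        _write_frame(rep_df, out / "screen_report.tsv", "\t", cfg)
        art["screen"] = ["screen_report.tsv"]

    if "dose" in stages:
        log.info("dose: curve fits, normalized AUC, classification")
        dose_df = read_dose_table(cfg.dose)
        rows = []
        for drug, grp in dose_df.groupby("drug", sort=True):
            fit = dr.fit_curve(grp)
            auc = dr.normalized_auc(points=grp)
            rows.append(dict(drug=drug, logIC50=fit.logIC50, sse=fit.sse,
                             converged=fit.converged, auc_norm=auc,
                             label=dr.classify_response(auc)))
        _write_frame(pd.DataFrame(rows), out / "dose_response.tsv", "\t", cfg)
        art["dose"] = ["dose_response.tsv"]

    if "associate" in stages:
        log.info("associate: mutation-drug LMM")
        zdf = _read_frame(cfg.zscores, "\t", {"sample", "drug", "z"})
        mut = _read_frame(cfg.mutations, "\t", {"sample"}).set_index("sample")
        table = assoc.mutation_drug_matrix(mut, zdf)
        _write_frame(table, out / "associations.tsv", "\t", cfg)
        art["associate"] = ["associations.tsv"]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
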