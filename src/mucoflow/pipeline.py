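"""End-to-end synthetic-to-report pipeline orchestration.

Runs simulate -> donor ranking -> diversity shifts -> mucus metrics ->
taxa-phenotype correlation -> assay quantification and writes tidy CSV
artifacts plus a JSON run manifest recording every numeric decision
(seed, normalization variant, improvement directions, bin widths,
pseudocounts) so a run is reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assay_quant import (
    enzyme_activity,
    fit_standard_curve,
    normalize_activities,
)
from .community_profiles import clr_transform, filter_low_abundance, relative_abundance
from .diversity_distance import shift_table
from .donor_selection import (
    DEFAULT_DIRECTIONS,
    rank_metabolic,
    rank_microbiota_shift,
    select_donors,
)
from .mucus_function import growth_rate, penetrability, penetrability_per_mouse
from .stats_core import correlate_taxa_vs_phenotype
from .synthetic_data import (
    SimConfig,
    gen_assay_plate,
    gen_cohort,
    gen_mouse_bead_images,
    gen_mucus_experiment,
    gen_paired_communities,
)

__all__ = ["ALL_STAGES", "PipelineConfig", "run_pipeline", "make_report"]

log = logging.getLogger("mucoflow")

ALL_STAGES = ("donors", "diversity", "mucus", "correlate", "assays")


@dataclasses.dataclass
class PipelineConfig:
    outdir: str
    simulation: SimConfig = dataclasses.field(default_factory=SimConfig)
    stages: tuple = ALL_STAGES
    top_metabolic: int = 10
    n_donors: int = 5
    zone_um: float = 10.0
    bin_um: float = 5.0
    clr_pseudocount: float = 1.0
    top_n_taxa: int = 30

    def __post_init__(self):
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def _write(frame: pd.DataFrame, path: Path) -> str:
    frame.to_csv(path)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    manifest: dict = {
        "version": __version__,
        "seed": sim.seed,
        "simulation": dataclasses.asdict(sim),
        "decisions": {
            "rank_combination": "mean-rank (Borda), ties share mean rank",
            "improvement_directions": dict(DEFAULT_DIRECTIONS),
            "unifrac_normalization": "proportion-weighted, normalized",
            "clr_pseudocount": config.clr_pseudocount,
            "penetrability_zone_um": config.zone_um,
            "surface_bin_um": config.bin_um,
            "top_metabolic": config.top_metabolic,
            "n_donors": config.n_donors,
            "top_n_taxa": config.top_n_taxa,
        },
        "stages": list(config.stages),
        "artifacts": {},
    }
    art = manifest["artifacts"]

    cohort, cohort_truth = gen_cohort(sim)
    art["cohort.csv"] = _write(cohort, out / "cohort.csv")
    truth_dict = {"cohort": cohort_truth.to_dict()}

    table = tree = None
    shifts = None
    if "donors" in config.stages or "diversity" in config.stages:
        table, tree, comm_truth = gen_paired_communities(sim)
        truth_dict["communities"] = comm_truth.to_dict()
        tree.write(str(out / "tree.nwk"))
        art["feature_table.tsv"] = _write(table.counts, out / "feature_table.tsv")

    if "donors" in config.stages:
        log.info("stage donors: ranking %d participants", len(cohort))
        metabolic = rank_metabolic(cohort)
        top = metabolic.ordered_ids()[: config.top_metabolic]
        pairs = {p: (f"{p}_pre", f"{p}_post") for p in top}
        shifts = shift_table(table, tree, pairs)
        art["shifts.csv"] = _write(shifts, out / "shifts.csv")
        gut = rank_microbiota_shift(shifts)
        donors, audit = select_donors(
            metabolic, gut, config.top_metabolic, config.n_donors
        )
        art["donor_audit.csv"] = _write(audit, out / "donor_audit.csv")
        manifest["donors"] = donors

    if "diversity" in config.stages:
        pairs = {
            p: (f"{p}_pre", f"{p}_post")
            for p in sorted({s.rsplit("_", 1)[0] for s in table.sample_ids})
        }
        all_shifts = shift_table(table, tree, pairs)
        art["all_shifts.csv"] = _write(all_shifts, out / "all_shifts.csv")

    if "mucus" in config.stages:
        thickness, mucus_truth = gen_mucus_experiment(sim)
        truth_dict["mucus"] = mucus_truth.to_dict()
        art["thickness.csv"] = _write(thickness.set_index("mouse_id"),
                                      out / "thickness.csv")
        rates = growth_rate(thickness)
        art["growth_rates.csv"] = _write(rates.to_frame(), out / "growth_rates.csv")
        clouds, bead_truths = gen_mouse_bead_images(sim, mouse_id="M1")
        results = [
            penetrability(c, zone_um=config.zone_um, bin_um=config.bin_um)
            for c in clouds
        ]
        per_mouse = penetrability_per_mouse(results)
        truth_dict["beads"] = [t.to_dict() for t in bead_truths]
        art["penetrability.csv"] = _write(per_mouse.to_frame(),
                                          out / "penetrability.csv")
        manifest["mucus"] = {
            "group_rates_recovered": {
                g: float(rates[[m for m in rates.index if m.startswith(g)]].mean())
                for g in sim.growth_rates
            },
            "penetrability_per_mouse": per_mouse.to_dict(),
        }

    if "correlate" in config.stages:
        if table is None:
            table, tree, comm_truth = gen_paired_communities(sim)
            truth_dict["communities"] = comm_truth.to_dict()
        filtered, _ = filter_low_abundance(table)
        clr = clr_transform(filtered, pseudocount=config.clr_pseudocount)
        rel = relative_abundance(filtered)
        # a synthetic per-sample phenotype keyed to the first taxon's CLR,
        # exercising the screen end to end
        pheno = clr.values_frame.iloc[:, 0]
        corr = correlate_taxa_vs_phenotype(
            clr, pheno, top_n=config.top_n_taxa, ranking=rel.values_frame
        )
        corr_frame = pd.DataFrame(
            [
                {
                    "taxon": r.label,
                    "rho": r.rho,
                    "p_value": r.p_value,
                    "p_adjusted": r.p_adjusted,
                }
                for r in corr
            ]
        ).set_index("taxon")
        art["correlations.csv"] = _write(corr_frame, out / "correlations.csv")

    if "assays" in config.stages:
        plate, assay_truth = gen_assay_plate(sim)
        truth_dict["assay"] = assay_truth.to_dict()
        art["plate.csv"] = _write(plate.set_index("well"), out / "plate.csv")
        standards = plate[plate.role == "standard"]
        curve = fit_standard_curve(standards[["x_value", "signal"]].to_numpy())
        acts = {}
        for enzyme, sub in plate[plate.role == "sample"].groupby("analyte"):
            res = enzyme_activity(
                sub["signal"].to_numpy(), curve,
                time_min=sim.assay_time_min, protein_mg=sim.assay_protein_mg,
                enzyme=str(enzyme),
            )
            acts[str(enzyme)] = res.activity
        shares = normalize_activities(acts)
        frame = pd.DataFrame({"activity": acts, "share": shares})
        frame.index.name = "enzyme"
        art["activities.csv"] = _write(frame, out / "activities.csv")
        manifest["assays"] = {
            "curve": {"slope": curve.slope, "intercept": curve.intercept,
                      "r_squared": curve.r_squared},
        }

    (out / "ground_truth.json").write_text(
        json.dumps(truth_dict, indent=2, sort_keys=True, default=float)
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest


def make_report(outdir) -> str:
    """Human-readable summary of a pipeline run's artifacts."""
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {out}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "mucoflow run report",
        "===================",
        f"version {manifest['version']}, seed {manifest['seed']}",
        "",
    ]

    def section(title, filename, fmt):
        lines.append(title)
        lines.append("-" * len(title))
        path = out / filename
        if not path.exists():
            lines.append("not run")
        else:
            fmt(path)
        lines.append("")

    def donors(path):
        audit = pd.read_csv(path, index_col=0)
        lines.append(audit.to_string())
        if "donors" in manifest:
            lines.append(f"selected donors: {', '.join(manifest['donors'])}")

    def rates(path):
        lines.append(pd.read_csv(path, index_col=0).to_string())

    def corr(path):
        frame = pd.read_csv(path, index_col=0).sort_values("p_value")
        lines.append(frame.head(10).to_string())

    section("Donor ranking", "donor_audit.csv", donors)
    section("Mucus growth rates (um/min)", "growth_rates.csv", rates)
    section("Penetrability (fraction within zone)", "penetrability.csv", rates)
    section("Top taxon-phenotype correlations", "correlations.csv", corr)
    section("Enzyme activities", "activities.csv", rates)
    text = "\n".join(lines)
    (out / "report.txt").write_text(text)
    return text
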