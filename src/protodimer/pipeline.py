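"""Stage orchestration and the consolidated run report.

Stages run in dependency order; a failing stage is recorded with its error
and independent stages still run.  The report is written both as JSON
(validating against the pydantic schema in this module) and as a short
human-readable text summary, together with the resolved configuration, so a
run can be reproduced from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import pydantic

from . import __version__
from .config import RunConfig, config_hash
from .conservation import column_stats, consensus, flag_conserved, read_alignment
from .csp import CSPConfig, compute_csp, map_csp, read_shift_table
from .errors import ProtodimerError
from .fitting import (
    MeltCurve,
    TitrationCurve,
    UreaCurve,
    fit_fp_binding,
    fit_two_state_chemical,
    fit_two_state_thermal,
)
from .geometry import (
    assign_secondary_structure,
    ensemble_rmsd,
    helix_axis_for_segment,
    interhelix_angle,
)
from .structure import NumberingMap, Selection, read_structure
from .surface import SASAParams, compute_sasa, find_hbonds, find_salt_bridges, interface_analysis
from .structure import apply_selection


class StageBlock(pydantic.BaseModel):
    status: str  # ok | error | skipped
    elapsed_s: float = 0.0
    error: str | None = None
    results: dict[str, Any] = {}


class Report(pydantic.BaseModel):
    """Consolidated, schema-validated run report."""

    version: str
    seed: int
    config_hash: str
    stages: dict[str, StageBlock]

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(self.model_dump_json(indent=2))
        lines = [f"protodimer {self.version}  seed={self.seed}  config={self.config_hash}"]
        for name, block in self.stages.items():
            lines.append(f"[{block.status:>7}] {name} ({block.elapsed_s:.2f} s)")
            if block.error:
                lines.append(f"          {block.error}")
            for key, val in block.results.items():
                if isinstance(val, float):
                    lines.append(f"          {key} = {val:.4g}")
                elif isinstance(val, (int, str)):
                    lines.append(f"          {key} = {val}")
        (out_dir / "report.txt").write_text("\n".join(lines) + "\n")


REPORT_SCHEMA = Report.model_json_schema()


def _run_surface(cfg: RunConfig, out_dir: Path) -> dict[str, Any]:
    stage = cfg.surface
    st = read_structure(stage.structure)
    params = SASAParams(probe_radius=stage.probe_radius, n_points=stage.n_points)
    numbering = NumberingMap(cfg.numbering_offset)

    refs = apply_selection(st, stage.model_index, Selection(atom_class="heavy"))
    sasa = compute_sasa(refs, params)
    report = interface_analysis(
        st, stage.model_index, tuple(stage.chains_a), tuple(stage.chains_b),
        params, stage.interface_cutoff,
    )
    bridges = find_salt_bridges(
        st, stage.model_index, stage.salt_bridge_cutoff, params=params
    )
    hbonds = find_hbonds(st, stage.model_index)

    rows = [
        {
            "chain": c, "file_num": n, "native_num": numbering.to_native(n),
            "sasa_A2": round(sasa.per_residue.get((c, n), 0.0), 2),
            "buried_A2": round(report.per_residue_buried.get((c, n), 0.0), 2),
            "interface": n in report.interface_residues.get(c, []),
        }
        for (c, n) in sorted(sasa.per_residue)
    ]
    pd.DataFrame(rows).to_csv(out_dir / "surface_per_residue.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "acidic": f"{b.acidic[0]}:{b.acidic[1]}:{b.acidic[2]}",
                "basic": f"{b.basic[0]}:{b.basic[1]}:{b.basic[2]}",
                "distance_A": round(b.distance, 2),
                "asa_ratio_pct": None if b.asa_ratio is None else round(b.asa_ratio, 1),
            }
            for b in bridges
        ]
    ).to_csv(out_dir / "salt_bridges.tsv", sep="\t", index=False)
    return {
        "total_sasa_A2": sasa.total,
        "buried_total_A2": report.buried_total_complexwide,
        "buried_per_chain_A2": report.buried_total_per_chain,
        "n_interface_residues": report.n_interface_residues,
        "n_salt_bridges": len(bridges),
        "n_hbonds": len(hbonds),
    }


def _run_ensemble(cfg: RunConfig, out_dir: Path) -> dict[str, Any]:
    stage = cfg.ensemble
    st = read_structure(stage.structure)
    numbering = NumberingMap(cfg.numbering_offset)
    ranges = tuple(tuple(r) for r in (stage.ordered_region or ()))
    sel = Selection(
        chains=None if stage.chains is None else tuple(stage.chains), ranges=ranges
    )
    bb_mean, bb_per = ensemble_rmsd(st, sel, "backbone", numbering)
    heavy_mean, heavy_per = ensemble_rmsd(st, sel, "heavy", numbering)
    pd.DataFrame(
        {"model": range(1, len(bb_per) + 1), "backbone_rmsd_A": bb_per, "heavy_rmsd_A": heavy_per}
    ).to_csv(out_dir / "ensemble_rmsd.tsv", sep="\t", index=False)
    return {
        "n_models": st.n_models,
        "backbone_rmsd_to_mean_A": bb_mean,
        "heavy_rmsd_to_mean_A": heavy_mean,
    }


def _run_geometry(cfg: RunConfig, out_dir: Path) -> dict[str, Any]:
    stage = cfg.geometry
    st = read_structure(stage.structure)
    numbering = NumberingMap(cfg.numbering_offset)
    ss = assign_secondary_structure(st, stage.model_index, numbering)
    pd.DataFrame(
        [{"kind": k, "chain": c, "start": a, "end": b} for k, c, a, b in ss.segments]
    ).to_csv(out_dir / "secondary_structure.tsv", sep="\t", index=False)
    helices = ss.of_kind("helix", stage.chain)
    results: dict[str, Any] = {
        "n_helices": len(helices),
        "n_strands": len(ss.of_kind("strand", stage.chain)),
        "segments": [list(s) for s in ss.segments if s[1] == stage.chain],
    }
    if len(helices) >= 2:
        ax1 = helix_axis_for_segment(
            st, stage.model_index, stage.chain, helices[0][2], helices[0][3], numbering
        )
        ax2 = helix_axis_for_segment(
            st, stage.model_index, stage.chain, helices[1][2], helices[1][3], numbering
        )
        results["interhelix_angle_deg"] = interhelix_angle(ax1, ax2)
    return results


def _run_csp(cfg: RunConfig, out_dir: Path) -> dict[str, Any]:
    stage = cfg.csp
    config = CSPConfig(
        nitrogen_weight=stage.nitrogen_weight,
        threshold=stage.threshold,
        formula_variant=stage.formula_variant,
    )
    free = read_shift_table(stage.free)
    bound = read_shift_table(stage.bound)
    result = compute_csp(free, bound, config)
    pd.DataFrame(
        [
            {"residue": r.native_num, "csp_ppm": round(r.d, 4),
             "significant": r.significant, "exchange": r.exchange}
            for r in result.records
        ]
    ).to_csv(out_dir / "csp.tsv", sep="\t", index=False)
    results: dict[str, Any] = {
        "n_residues": len(result.records),
        "n_significant": len(result.significant),
        "significant": [r.native_num for r in result.significant],
        "only_in_free": result.only_in_free,
        "only_in_bound": result.only_in_bound,
    }
    if stage.structure:
        st = read_structure(stage.structure)
        summary = map_csp(
            result, st, NumberingMap(cfg.numbering_offset),
            out_dir / "csp_mapped.pdb", stage.region,
        )
        results["unmapped"] = summary.unmapped
        if summary.fraction_in_region is not None:
            results["fraction_significant_in_region"] = summary.fraction_in_region
    return results


def _run_fit(cfg: RunConfig, out_dir: Path) -> dict[str, Any]:
    stage = cfg.fit
    results: dict[str, Any] = {}
    if stage.titration:
        df = pd.read_csv(stage.titration, sep="\t")
        curve = TitrationCurve(df["conc_uM"].to_numpy(), df["polarization_mP"].to_numpy())
        fit = fit_fp_binding(curve, stage.binding_model, stage.tracer_conc_um)
        results["binding"] = {
            "kd_uM": fit.kd, "kd_se_uM": fit.kd_se,
            "p_free_mP": fit.p_free, "p_bound_mP": fit.p_bound,
            "model": fit.model, "warnings": fit.warnings,
        }
    if stage.melt:
        df = pd.read_csv(stage.melt, sep="\t")
        curve = MeltCurve(df["temperature_C"].to_numpy(), df["signal"].to_numpy())
        fit = fit_two_state_thermal(curve)
        results["thermal"] = {
            "tm_C": fit.midpoint, "tm_se_C": fit.midpoint_se,
            "dh_kJ_mol": fit.slope_term,
        }
    if stage.urea:
        df = pd.read_csv(stage.urea, sep="\t")
        curve = UreaCurve(df["urea_M"].to_numpy(), df["signal"].to_numpy())
        fit = fit_two_state_chemical(curve)
        results["chemical"] = {
            "cm_M": fit.midpoint, "cm_se_M": fit.midpoint_se,
            "m_kJ_mol_M": fit.slope_term,
        }
    if not results:
        raise ProtodimerError("fit stage enabled but no curve file given")
    return results


def _run_conservation(cfg: RunConfig, out_dir: Path) -> dict[str, Any]:
    stage = cfg.conservation
    msa = read_alignment(stage.alignment)
    stats = column_stats(msa, stage.reference_id, reference_start=stage.reference_start)
    flagged = flag_conserved(stats, stage.threshold)
    pd.DataFrame(
        [
            {
                "column": s.column, "native_num": s.native_num,
                "gap_fraction": round(s.gap_fraction, 3),
                "information_bits": round(s.information, 3),
                **{f"frac_{k}": round(v, 3) for k, v in s.class_fractions.items()},
            }
            for s in stats
        ]
    ).to_csv(out_dir / "conservation.tsv", sep="\t", index=False)
    return {
        "n_sequences": msa.n_sequences,
        "n_columns": msa.n_columns,
        "consensus": consensus(msa),
        "flagged": [[n, c] for n, c in flagged],
        "n_flagged": len(flagged),
    }


_STAGES = {
    "surface": _run_surface,
    "ensemble": _run_ensemble,
    "geometry": _run_geometry,
    "csp": _run_csp,
    "fit": _run_fit,
    "conservation": _run_conservation,
}


def run_pipeline(config: RunConfig) -> Report:
    """Run all enabled stages and write the consolidated report.

    Stage failures are recorded in the report (status "error") without
    aborting independent stages.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config_resolved.json").write_text(config.model_dump_json(indent=2))

    blocks: dict[str, StageBlock] = {}
    for name in config.enabled_stages():
        t0 = time.perf_counter()
        try:
            results = _STAGES[name](config, out_dir)
            blocks[name] = StageBlock(
                status="ok", elapsed_s=time.perf_counter() - t0,
                results=json.loads(json.dumps(results, default=_jsonable)),
            )
        except (ProtodimerError, ValueError, OSError) as exc:
            blocks[name] = StageBlock(
                status="error", elapsed_s=time.perf_counter() - t0, error=str(exc)
            )
    report = Report(
        version=__version__,
        seed=config.seed,
        config_hash=config_hash(config),
        stages=blocks,
    )
    report.write(out_dir)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)
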