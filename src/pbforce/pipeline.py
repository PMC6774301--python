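"""End-to-end orchestration: read/generate -> axis -> prune -> profiles -> classify.

The pipeline takes a set of two-partner complexes (PQR files and/or named
synthetic fixtures), finds each complex's separation axis, applies the three
geometry filters, computes F_int/F_ene profiles under the configured
dielectric models for the survivors, classifies every profile, and writes a
deterministic set of artifacts: a pruning report, per-profile TSV tables, a
JSON summary with per-category counts and the polarity cross-tabulation
(same / zero-on-one / opposite, for net and interface charge), and a
manifest listing every file written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import DEFAULT_TOL, classify_profile
from .dielectric import DielectricParams
from .errors import PBForceError
from .forces import build_force_profile, profile_grid
from .geometry import (
    CLASH_CUTOFF,
    OVERLAP_FRACTION,
    PAIR_CUTOFF,
    SLOPE_THRESHOLD,
    find_interface_pairs,
    orient_axis,
    prune_complex,
    separation_direction,
)
from .grids import DEFAULT_FILL, DEFAULT_SPACING
from .solver import SolverSettings
from .structures import (
    ComplexStructure,
    classify_polarity,
    interface_charge,
    net_charge,
    read_pqr,
    write_pqr,
)
from .synthetic import shipped_fixtures

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    inputs: list[str] = field(default_factory=list)  # PQR paths
    synthetic: list[str] = field(default_factory=lambda: ["all"])
    models: list[str] = field(default_factory=lambda: ["two_dielectric", "gaussian"])
    sigmas: list[float] = field(default_factory=lambda: [0.96])
    eps_in: float = 2.0
    eps_out: float = 80.0
    probe_radius: float = 1.4
    spacing: float = DEFAULT_SPACING
    fill: float = DEFAULT_FILL
    distances: list[float] = field(default_factory=lambda: [float(k) for k in range(11)])
    pair_cutoff: float = PAIR_CUTOFF
    overlap_fraction: float = OVERLAP_FRACTION
    clash_cutoff: float = CLASH_CUTOFF
    slope_threshold: float = SLOPE_THRESHOLD
    solver_tolerance: float = 1e-8
    max_iterations: int = 20000
    classify_tol: float = DEFAULT_TOL
    polarity_tol: float = 0.01
    write_snapshots: bool = False
    output_dir: str = "pbforce_out"

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in ("two_dielectric", "gaussian"):
                raise ValueError(f"unknown dielectric model {m!r}")
        if not self.distances or self.distances[0] != 0:
            raise ValueError("distance list must start at 0")
        if not self.inputs and not self.synthetic:
            raise ValueError("no inputs: give PQR paths or synthetic fixture names")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def dielectric_params(self) -> list[DielectricParams]:
        out = []
        for m in self.models:
            if m == "two_dielectric":
                out.append(
                    DielectricParams(
                        eps_in=self.eps_in, eps_out=self.eps_out,
                        probe_radius=self.probe_radius, model="two_dielectric",
                    )
                )
            else:
                for s in self.sigmas:
                    out.append(
                        DielectricParams(
                            eps_in=self.eps_in, eps_out=self.eps_out,
                            sigma=s, model="gaussian",
                        )
                    )
        return out

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(
            tolerance=self.solver_tolerance, max_iterations=self.max_iterations
        )


def load_complexes(config: RunConfig) -> list[ComplexStructure]:
    complexes: list[ComplexStructure] = []
    for path in config.inputs:
        complexes.append(read_pqr(path))
    fixtures = shipped_fixtures()
    names = list(fixtures) if "all" in config.synthetic else config.synthetic
    for name in names:
        if name not in fixtures:
            raise PBForceError(
                f"unknown synthetic fixture {name!r}; available: {sorted(fixtures)}"
            )
        complexes.append(fixtures[name].build())
    return complexes


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write artifacts; returns the JSON-ready summary.

    A failure in one complex is recorded in the summary and the pipeline
    continues with the remaining complexes.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def record(path: Path) -> Path:
        written.append(str(path.relative_to(out)))
        return path

    with open(record(out / "config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)

    pruning_rows = []
    profile_rows: list[pd.DataFrame] = []
    summary: dict = {"complexes": {}, "category_counts": {}, "errors": {}}
    params_list = config.dielectric_params()
    settings = config.solver_settings()

    for cx in load_complexes(config):
        try:
            pairs = find_interface_pairs(cx, cutoff=config.pair_cutoff)
            axis = orient_axis(cx, separation_direction(pairs))
            report = prune_complex(
                cx, axis, pairs,
                overlap_threshold=config.overlap_fraction,
                clash_cutoff=config.clash_cutoff,
                slope_threshold=config.slope_threshold,
            )
            pruning_rows.append(
                {
                    "complex": cx.name, "n_pairs": report.n_pairs,
                    "fraction_increased": report.fraction_increased,
                    "min_cross_distance": report.min_cross_distance,
                    "slope": report.slope, "verdict": report.verdict,
                }
            )
            qa, qb = net_charge(cx.partner_a), net_charge(cx.partner_b)
            iqa, iqb = interface_charge(cx, pairs)
            entry: dict = {
                "kept": report.keep,
                "verdict": report.verdict,
                "net_charge": [qa, qb],
                "interface_charge": [iqa, iqb],
                "net_polarity": classify_polarity(qa, qb, config.polarity_tol),
                "interface_polarity": classify_polarity(iqa, iqb, config.polarity_tol),
                "profiles": {},
            }
            summary["complexes"][cx.name] = entry
            if not report.keep:
                logger.info("%s rejected (%s)", cx.name, report.verdict)
                continue
            grid = profile_grid(
                cx, axis, max_distance=max(config.distances),
                spacing=config.spacing, fill=config.fill,
            )
            if config.write_snapshots:
                from .geometry import separate

                snap_dir = out / "snapshots"
                snap_dir.mkdir(exist_ok=True)
                for d in config.distances:
                    cfg_d = separate(cx, axis, d)
                    write_pqr(cfg_d.complex, record(snap_dir / f"{cx.name}_d{d:g}.pqr"))
            for params in params_list:
                profile = build_force_profile(
                    cx, axis, params, settings,
                    distances=config.distances, grid=grid,
                )
                cat = classify_profile(
                    profile.distances, profile.f_int, tol=config.classify_tol
                )
                profile_rows.append(profile.to_dataframe())
                entry["profiles"][params.tag] = {
                    "category": cat.label.value,
                    "d_min": cat.d_min,
                    "f_at_bound": cat.f_at_bound,
                    "f_int": profile.f_int,
                    "f_ene": profile.f_ene,
                    "delta_e": profile.delta_e,
                }
                logger.info("%s [%s] -> %s", cx.name, params.tag, cat.label.value)
        except PBForceError as exc:
            logger.warning("%s failed: %s", cx.name, exc)
            summary["errors"][cx.name] = str(exc)

    if pruning_rows:
        pd.DataFrame(pruning_rows).to_csv(
            record(out / "pruning.tsv"), sep="\t", index=False, float_format="%.6g"
        )
    if profile_rows:
        pd.concat(profile_rows, ignore_index=True).to_csv(
            record(out / "profiles.tsv"), sep="\t", index=False, float_format="%.6g"
        )

    summary["category_counts"] = _category_counts(summary["complexes"])
    summary["polarity_table"] = _polarity_table(summary["complexes"])
    with open(record(out / "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"files": sorted(written + ["manifest.json"])}, fh, indent=2)
    return summary


def _category_counts(complexes: dict) -> dict:
    counts: dict[str, dict[str, int]] = {}
    for entry in complexes.values():
        for tag, prof in entry.get("profiles", {}).items():
            counts.setdefault(tag, {})
            cat = prof["category"]
            counts[tag][cat] = counts[tag].get(cat, 0) + 1
    return counts


def _polarity_table(complexes: dict) -> dict:
    """Per-category polarity cross-tabulation of net and interface charge."""
    table: dict[str, dict] = {}
    for entry in complexes.values():
        if not entry.get("kept"):
            continue
        for tag, prof in entry["profiles"].items():
            row = table.setdefault(tag, {}).setdefault(
                prof["category"],
                {
                    "n": 0,
                    "net": {"same": 0, "zero_on_one": 0, "opposite": 0},
                    "interface": {"same": 0, "zero_on_one": 0, "opposite": 0},
                },
            )
            row["n"] += 1
            row["net"][entry["net_polarity"]] += 1
            row["interface"][entry["interface_polarity"]] += 1
    return table
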