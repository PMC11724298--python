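"""End-to-end orchestration: simulate -> detect -> equilibrium -> kinetics -> profile.

The library layer behind the command-line interface.  A configuration
(dict, JSON or YAML) names the constructs (presets or explicit parameter
blocks), the ramp protocol, detector settings and the root seed; the
pipeline derives per-stage random streams from that one seed, so a rerun of
the same configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model
from .detect import DetectorConfig, analyze_half_cycle
from .equilibrium import EquilibriumResult, analyze_equilibrium, stabilization_dG
from .io import DatasetManifest, segment_cycles, write_events, write_trace
from .kinetics import KineticsResult, analyze_kinetics, attempt_rate, barrier_per_bp
from .model import ConstructModel, RampProtocol, construct_preset
from .profile import build_profile_at_ftr, classify_metastability, tilt_to_zero_force
from .simulate import Trace, simulate_dataset

__all__ = [
    "PipelineConfig",
    "DetectionResult",
    "detect_dataset",
    "run_pipeline",
]

_ALLOWED_KEYS = {
    "constructs",
    "protocol",
    "detector",
    "seed",
    "reference",
    "bin_width",
    "fit_window",
    "save_traces",
    "kbt",
    "x_bs",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``constructs`` may be preset names or explicit parameter dicts; the
    ``reference`` construct anchors the stabilization free energies.  The
    ``seed`` is mandatory whenever traces are simulated.
    """

    constructs: list
    protocol: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    seed: int | None = None
    reference: str | None = None
    bin_width: float = 0.25
    fit_window: float = 1.2
    save_traces: bool = False
    kbt: float = model.DEFAULT_KBT
    x_bs: float = model.X_BS_PER_BP

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "constructs" not in raw or not raw["constructs"]:
            raise ValueError("config must name at least one construct")
        if raw.get("seed") is None:
            raise ValueError("config must set a seed for simulation runs")
        return cls(**raw)

    def build_constructs(self) -> list[tuple[ConstructModel, int]]:
        """Resolve (construct, n_cycles) pairs; presets default to their
        published cycle counts."""
        out = []
        for item in self.constructs:
            if isinstance(item, str):
                c = construct_preset(item, kbt=self.kbt)
                m = model.EQUILIBRIUM_TABLE[item]["m"]
            else:
                item = dict(item)
                m = int(item.pop("n_cycles", 50))
                name = item.get("name", "custom")
                if set(item) == {"name"} or set(item) <= {"name", "n_cycles"}:
                    c = construct_preset(name, kbt=self.kbt)
                else:
                    item.setdefault("fray_slope", 1.0)
                    if "b_branch" in item:
                        item["b_branch"] = tuple(item["b_branch"])
                    c = ConstructModel(**item)
            out.append((c, m))
        return out

    def build_protocol(self) -> RampProtocol:
        return RampProtocol(seed=self.seed, **self.protocol)

    def build_detector(self) -> DetectorConfig:
        return DetectorConfig(**self.detector)


@dataclass
class DetectionResult:
    """Detector output for one construct's trace collection."""

    events: pd.DataFrame
    dwells: list
    occupancy: pd.DataFrame
    n_cycles: int
    n_usable_halves: int
    n_halves: int


def detect_dataset(trace: Trace, config: DetectorConfig = DetectorConfig()) -> DetectionResult:
    """Run branch fitting, event calling and dwell extraction over a trace."""
    halves = segment_cycles(trace)
    all_events, all_dwells = [], []
    occ_force, occ_state, occ_cycle = [], [], []
    usable = 0
    for h in halves:
        if len(h) < 100:  # stray fragment at a cycle boundary
            continue
        branches, events, dwells, state = analyze_half_cycle(h, config)
        if branches.usable:
            usable += 1
            if len(events):
                all_events.append(events)
            all_dwells.extend(dwells)
            occ_force.append(h.force)
            occ_state.append(state)
            occ_cycle.append(np.full(len(h), h.cycle_id))
    from .simulate import EVENT_COLUMNS

    events = (
        pd.concat(all_events).sort_values(["cycle", "time_s"]).reset_index(drop=True)
        if all_events
        else pd.DataFrame(columns=EVENT_COLUMNS)
    )
    occupancy = pd.DataFrame(
        {
            "cycle": np.concatenate(occ_cycle) if occ_cycle else [],
            "force": np.concatenate(occ_force) if occ_force else [],
            "in_s": np.concatenate(occ_state) if occ_state else [],
        }
    )
    n_cycles = int(np.unique(trace.cycle_id).size)
    return DetectionResult(
        events=events,
        dwells=all_dwells,
        occupancy=occupancy,
        n_cycles=n_cycles,
        n_usable_halves=usable,
        n_halves=len(halves),
    )


def run_pipeline(raw_config: dict, outdir: str | Path | None = None) -> dict:
    """Run the full chain and (optionally) write the report bundle.

    Returns a dict with per-construct equilibrium and kinetics results, the
    cross-construct barrier/attempt-rate estimates and the free-energy
    profiles.  With ``outdir`` set, writes ``table1.json/.csv``,
    ``table2.json/.csv``, ``profile.csv``, ``manifest.json`` and ``run.log``.
    """
    cfg = PipelineConfig.from_dict(raw_config)
    protocol = cfg.build_protocol()
    detector = cfg.build_detector()
    pairs = cfg.build_constructs()
    log: list[str] = [f"pipeline seed {cfg.seed}"]

    datasets = simulate_dataset(
        [c for c, _ in pairs], protocol, [m for _, m in pairs], cfg.seed, cfg.kbt
    )
    eq_rows: dict[str, EquilibriumResult] = {}
    kin_rows: dict[str, KineticsResult] = {}
    traces = {}
    for construct, m in pairs:
        trace, truth = datasets[construct.name]
        traces[construct.name] = trace
        det = detect_dataset(trace, detector)
        log.append(
            f"{construct.name}: {det.n_usable_halves}/{det.n_halves} usable "
            f"half-cycles, {len(det.events)} events"
        )
        eq = analyze_equilibrium(
            det.events,
            det.occupancy,
            construct=construct.name,
            m=m,
            kbt=cfg.kbt,
            x_bs=cfg.x_bs,
            seed=cfg.seed,
        )
        kin = analyze_kinetics(
            det.events,
            det.dwells,
            protocol.loading_rate,
            eq.f_tr_hat,
            m,
            eq.n_hat,
            construct=construct.name,
            kbt=cfg.kbt,
            bin_width=cfg.bin_width,
            window=cfg.fit_window,
        )
        eq_rows[construct.name] = eq
        kin_rows[construct.name] = kin

    # stabilization free energies against the reference construct
    ref_name = cfg.reference or pairs[0][0].name
    if ref_name in eq_rows:
        g_ref = eq_rows[ref_name].g_hat
        for name, eq in eq_rows.items():
            eq.dg = stabilization_dG(eq.g_bs, eq.n_hat, g_ref)
            eq.dg_sem = float(
                np.hypot(eq.g_bs_sem, eq.n_hat * eq_rows[ref_name].g_sem)
            )

    # cross-construct barrier scaling and attempt rate
    result: dict = {
        "equilibrium": {k: v.to_dict() for k, v in eq_rows.items()},
        "kinetics": {k: v.to_dict() for k, v in kin_rows.items()},
    }
    if len(kin_rows) >= 2:
        ns = [eq_rows[k].n_hat for k in kin_rows]
        Ns = [kin_rows[k].n_per_cycle for k in kin_rows]
        if min(Ns) > 0 and np.ptp(ns) > 0:
            g_ts, g_ts_se = barrier_per_bp(ns, Ns)
            result["g_ts"] = g_ts
            result["g_ts_se"] = g_ts_se
            k_ftr = float(np.mean([kin_rows[k].k_at_ftr for k in kin_rows]))
            result["k0_bs"] = attempt_rate(k_ftr, float(np.mean(ns)), max(g_ts, 0.0))

    # per-construct free-energy profiles (per-bp)
    profiles = {}
    for name, kin in kin_rows.items():
        eq = eq_rows[name]
        g_ts_pp = result.get("g_ts", np.nan)
        if not np.isfinite(g_ts_pp):
            continue
        prof = build_profile_at_ftr(
            g_ts=max(g_ts_pp, 1e-3),
            x_ts=kin.xb_per_bp,
            x_bs=cfg.x_bs,
            kbt=cfg.kbt,
        )
        prof = tilt_to_zero_force(prof, eq.f_tr_hat, cfg.kbt)
        meta_ok, depth = classify_metastability(prof)
        profiles[name] = {
            "profile": prof,
            "s_metastable_at_zero": bool(meta_ok),
            "depth": float(depth),
        }
    result["profiles"] = profiles

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_reports(result, traces, cfg, protocol, outdir, log)
    return result


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_reports(result, traces, cfg, protocol, outdir: Path, log: list[str]) -> None:
    t1 = result["equilibrium"]
    t2 = result["kinetics"]
    with open(outdir / "table1.json", "w") as fh:
        json.dump(t1, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(outdir / "table2.json", "w") as fh:
        extra = {k: result[k] for k in ("g_ts", "g_ts_se", "k0_bs") if k in result}
        json.dump({"rows": t2, **extra}, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    pd.DataFrame(t1).T.to_csv(outdir / "table1.csv", float_format="%.6g")
    pd.DataFrame(t2).T.to_csv(outdir / "table2.csv", float_format="%.6g")
    prof_rows = []
    for name, p in result["profiles"].items():
        prof = p["profile"]
        for x, g1, g0 in zip(prof.x, prof.g_at_ftr, prof.g_at_zero):
            prof_rows.append(
                {"construct": name, "x_nm_per_bp": x, "g_at_Ftr_kBT": g1, "g_at_zero_kBT": g0}
            )
    if prof_rows:
        pd.DataFrame(prof_rows).to_csv(outdir / "profile.csv", index=False, float_format="%.6g")
    manifest_traces = []
    for name, trace in traces.items():
        entry = {"construct": name, "cycles": int(trace.meta.get("cycle_count", 0))}
        if cfg.save_traces:
            path = outdir / f"trace_{name.replace('/', '_')}.tsv"
            write_trace(trace, path)
            entry["file"] = path.name
        manifest_traces.append(entry)
    DatasetManifest(traces=manifest_traces, protocol=asdict(protocol)).save(
        outdir / "manifest.json"
    )
    (outdir / "run.log").write_text("\n".join(log) + "\n")
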