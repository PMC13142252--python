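"""End-to-end orchestration of the trajectory and assay analyses.

A run takes one configuration (see :mod:`fshrdyn.config`) and one
global seed, simulates (or loads) every declared system / ligand-state
/ replicate trajectory, then applies the activation-index, blocking,
microswitch-distance and contact analyses per replicate and the assay
statistics once, writing TSV tables plus a JSON summary.  Every output
carries the config hash; a MANIFEST lists all files and marks
incomplete runs.  Per-replicate seeds are derived from the global seed
via ``SeedSequence([seed, system_index, state_index, replicate_index])``
so adding a replicate or system never perturbs the seeds of earlier
ones.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from fshrdyn import __version__
from fshrdyn.activation import (
    ActivationModel,
    StateThresholds,
    compute_index,
    distribution,
    occupancy,
    calibrated_model,
)
from fshrdyn.assaystats import (
    FourPLFit,
    fit_4pl,
    mi_ratio_contrast,
    simulate_assay,
    simulate_densitometry,
)
from fshrdyn.blocking import blocking_curve, plateau
from fshrdyn.config import config_hash, default_config
from fshrdyn.contacts import ContactConfig, compare_maps, occupancy_map
from fshrdyn.microswitch import (
    DistancePair,
    distance_distribution,
    overlap_coefficient,
    pair_distance_series,
    shift_vs_reference,
)
from fshrdyn.synth import (
    DynamicsParams,
    build_bundle,
    default_geometry,
    place_ligand,
    simulate,
)
from fshrdyn.trajio import ReplicateSet, read_trajectory, write_trajectory

logger = logging.getLogger(__name__)

STAGES = ("simulate", "a100", "blocking", "distances", "contacts", "assay", "report")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def _write_tsv(path: Path, header: list[str], rows, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(
                _fmt(v) if isinstance(v, float) else str(v) for v in row
            ) + "\n")


def replicate_seed(global_seed: int, sys_idx: int, state_idx: int, rep_idx: int) -> int:
    """Stable per-replicate seed, independent of other replicates."""
    ss = np.random.SeedSequence([global_seed, sys_idx, state_idx, rep_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _pair_from_name(name: str) -> DistancePair:
    a, b = name.split("-")
    return DistancePair.from_helices(a, b)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, out: Path, cfg_hash: str) -> dict[tuple[str, str], ReplicateSet]:
    """Generate every declared replicate; write PDBs and ground-truth TSVs."""
    geometry = default_geometry()
    n_frames = int(config["n_frames"])
    helix_length = int(config["helix_length"])
    n_rep = int(config["n_replicates"])
    base_dyn = dict(config["dynamics"])
    pocket = [int(r) for r in config["pocket_residues"]]
    sets: dict[tuple[str, str], ReplicateSet] = {}
    for sys_idx, system in enumerate(config["systems"]):
        label = system["label"]
        dyn_kwargs = dict(base_dyn)
        dyn_kwargs.update(system.get("dynamics", {}))
        for state_idx, lig_state in enumerate(system["ligand_states"]):
            apo = build_bundle(geometry, helix_length=helix_length, state="active")
            structure = (
                place_ligand(apo, pocket, contact_distance=0.95 * config["contact"]["cutoff"],
                             seed=replicate_seed(config["seed"], sys_idx, state_idx, 999))
                if lig_state == "holo" else apo
            )
            replicates = []
            for rep_idx in range(n_rep):
                seed = replicate_seed(config["seed"], sys_idx, state_idx, rep_idx)
                dynamics = DynamicsParams(seed=seed, **dyn_kwargs)
                traj, truth = simulate(
                    geometry, dynamics, n_frames,
                    helix_length=helix_length, structure=structure,
                )
                replicates.append(traj)
                tag = f"{label}_{lig_state}_R{rep_idx + 1}"
                write_trajectory(out / f"traj_{tag}.pdb", traj)
                _write_tsv(
                    out / f"truth_{tag}.tsv",
                    ["frame", "time_ns", "hidden_state"],
                    [(i, float(traj.times[i]), truth.states[i])
                     for i in range(traj.n_frames)],
                    cfg_hash,
                )
            sets[(label, lig_state)] = ReplicateSet(label, lig_state, replicates)
    return sets


def load_simulated(config: dict, out: Path) -> dict[tuple[str, str], ReplicateSet]:
    """Re-read the trajectories a previous ``simulate`` stage wrote."""
    geometry = default_geometry()
    helix_length = int(config["helix_length"])
    pocket = [int(r) for r in config["pocket_residues"]]
    dt = float(config["dynamics"]["dt"])
    sets: dict[tuple[str, str], ReplicateSet] = {}
    for sys_idx, system in enumerate(config["systems"]):
        label = system["label"]
        for state_idx, lig_state in enumerate(system["ligand_states"]):
            apo = build_bundle(geometry, helix_length=helix_length, state="active")
            structure = (
                place_ligand(apo, pocket, contact_distance=0.95 * config["contact"]["cutoff"],
                             seed=replicate_seed(config["seed"], sys_idx, state_idx, 999))
                if lig_state == "holo" else apo
            )
            replicates = []
            for rep_idx in range(int(config["n_replicates"])):
                tag = f"{label}_{lig_state}_R{rep_idx + 1}"
                path = out / f"traj_{tag}.pdb"
                if not path.exists():
                    raise FileNotFoundError(
                        f"{path} not found; run the simulate stage first"
                    )
                replicates.append(read_trajectory(path, structure, dt=dt))
            sets[(label, lig_state)] = ReplicateSet(label, lig_state, replicates)
    return sets


def _activation_model(config: dict, helix_length: int) -> ActivationModel:
    from fshrdyn.microswitch import helix_anchor

    if config["activation_model"] == "auto":
        geometry = default_geometry()
        active = build_bundle(geometry, helix_length=helix_length, state="active")
        inactive = build_bundle(geometry, helix_length=helix_length, state="inactive")
        anchor_pairs = []
        for name in config["pairs"]:
            a, b = name.split("-")
            anchor_pairs.append((helix_anchor(active, a), helix_anchor(active, b)))
        return calibrated_model(active, inactive, anchor_pairs)
    return ActivationModel.from_config(config["activation_model"])


def stage_a100(
    config: dict, out: Path, cfg_hash: str,
    sets: dict[tuple[str, str], ReplicateSet],
) -> dict:
    """Per-replicate activation-index series, labels, occupancies, modes."""
    thr = StateThresholds(**config["thresholds"])
    model = _activation_model(config, int(config["helix_length"]))
    summary: dict = {}
    for (label, lig_state), rset in sets.items():
        for rep_name, traj in zip(rset.labels(), rset):
            tag = f"{label}_{lig_state}_{rep_name}"
            series = compute_index(traj, model, thr)
            _write_tsv(
                out / f"index_{tag}.tsv",
                ["frame", "time_ns", "index", "label"],
                [(i, float(series.times[i]), float(series.values[i]),
                  series.labels[i]) for i in range(len(series))],
                cfg_hash,
            )
            dist = distribution(series)
            summary[tag] = {
                "mean": round(dist.mean, 6),
                "sd_blocking": round(dist.sd, 6),
                "sd_converged": bool(dist.sd_converged),
                "modes": [round(float(m), 3) for m in dist.modes],
                "occupancy": {k: round(v, 6) for k, v in occupancy(series).items()},
            }
    return summary


def stage_blocking(
    config: dict, out: Path, cfg_hash: str,
    sets: dict[tuple[str, str], ReplicateSet],
) -> dict:
    """Blocking curves of the activation index per replicate."""
    thr = StateThresholds(**config["thresholds"])
    model = _activation_model(config, int(config["helix_length"]))
    summary: dict = {}
    for (label, lig_state), rset in sets.items():
        for rep_name, traj in zip(rset.labels(), rset):
            tag = f"{label}_{lig_state}_{rep_name}"
            series = compute_index(traj, model, thr)
            curve = blocking_curve(series.values)
            _write_tsv(
                out / f"blocking_{tag}.tsv",
                ["level", "n_blocks", "sd", "sd_err"],
                [(int(l), int(curve.n_blocks[l]), float(curve.sd[l]),
                  float(curve.sd_err[l])) for l in curve.levels],
                cfg_hash,
            )
            level, sd, conv = plateau(curve)
            summary[tag] = {"plateau_level": level, "sd": round(sd, 6),
                            "converged": bool(conv)}
    return summary


def stage_distances(
    config: dict, out: Path, cfg_hash: str,
    sets: dict[tuple[str, str], ReplicateSet],
) -> dict:
    """Microswitch distance series, shifts vs reference, apo/holo overlap."""
    pairs = [_pair_from_name(n) for n in config["pairs"]]
    refs = {k: float(v) for k, v in config["reference_distances"].items()}
    summary: dict = {}
    pooled: dict[tuple[str, str, str], np.ndarray] = {}
    for (label, lig_state), rset in sets.items():
        for rep_name, traj in zip(rset.labels(), rset):
            tag = f"{label}_{lig_state}_{rep_name}"
            per_pair = {}
            for pair in pairs:
                series = pair_distance_series(traj, pair)
                _write_tsv(
                    out / f"dist_{pair.name}_{tag}.tsv",
                    ["frame", "time_ns", "distance_A"],
                    [(i, float(traj.times[i]), float(series[i]))
                     for i in range(len(series))],
                    cfg_hash,
                )
                dist = distance_distribution(series)
                entry = {"primary_mode": round(dist.primary_mode, 3),
                         "mean": round(dist.mean, 6)}
                if pair.name in refs:
                    entry["shift_vs_reference"] = round(
                        shift_vs_reference(dist, refs, pair.name), 3)
                per_pair[pair.name] = entry
                key = (label, lig_state, pair.name)
                pooled[key] = (
                    np.concatenate([pooled[key], series]) if key in pooled else series
                )
            summary[tag] = per_pair
    # apo/holo overlap per system and pair, on pooled replicates
    overlaps: dict = {}
    for system in config["systems"]:
        label = system["label"]
        if {"apo", "holo"} <= set(system["ligand_states"]):
            for pair in pairs:
                a = pooled[(label, "apo", pair.name)]
                b = pooled[(label, "holo", pair.name)]
                overlaps[f"{label}:{pair.name}"] = round(
                    overlap_coefficient(a, b), 4)
    summary["apo_holo_overlap"] = overlaps
    return summary


def stage_contacts(
    config: dict, out: Path, cfg_hash: str,
    sets: dict[tuple[str, str], ReplicateSet],
) -> dict:
    """Ligand contact-occupancy maps for holo systems, plus comparison."""
    ccfg = ContactConfig(**config["contact"])
    maps = []
    summary: dict = {}
    for (label, lig_state), rset in sets.items():
        if lig_state != "holo":
            continue
        for rep_name, traj in zip(rset.labels(), rset):
            cmap = occupancy_map(traj, ccfg, system=label, replicate=rep_name)
            maps.append(cmap)
            tag = f"{label}_{rep_name}"
            _write_tsv(
                out / f"contacts_{tag}.tsv",
                ["residue", "resname", "occupancy"],
                [(r, cmap.res_names.get(r, "?"), float(f))
                 for r, f in cmap.occupancy.items()],
                cfg_hash,
            )
            summary[tag] = {
                "persistent": cmap.persistent(ccfg.min_persistence),
                "n_frames": cmap.n_frames,
            }
    if len(maps) >= 2:
        table = compare_maps(maps, ccfg.min_persistence)
        rows = [
            tuple([int(r)] + [bool(v) for v in table.loc[r]])
            for r in table.index
        ]
        _write_tsv(
            out / "contact_comparison.tsv",
            ["residue"] + [f"{s}_{r}" for s, r in table.columns],
            rows,
            cfg_hash,
        )
        summary["diff_residues"] = table.attrs["diff"]
    return summary


def stage_assay(config: dict, out: Path, cfg_hash: str) -> dict:
    """Synthetic dose-response fits and M/I densitometry contrast."""
    acfg = config["assay"]
    seed_base = int(config["seed"])
    summary: dict = {}
    for i, (name, block) in enumerate(sorted(acfg["dose_response"].items())):
        doses = np.logspace(
            np.log10(block["dose_min"]), np.log10(block["dose_max"]),
            int(block["n_doses"]),
        )
        truth = FourPLFit(block["bottom"], block["top"], block["ec50"], block["hill"])
        data = simulate_assay(
            truth, doses, cv=float(acfg["cv"]),
            n_replicates=int(acfg["n_replicates"]),
            seed=replicate_seed(seed_base, 100, i, 0),
        )
        fit = fit_4pl(data)
        _write_tsv(
            out / f"dose_response_{name}.tsv",
            ["dose"] + [f"rep{r + 1}" for r in range(data.responses.shape[0])],
            [tuple([float(d)] + [float(v) for v in data.responses[:, j]])
             for j, d in enumerate(data.doses)],
            cfg_hash,
        )
        summary[name] = {
            "ec50_true": block["ec50"],
            "ec50_fit": round(fit.ec50, 6),
            "ec50_se": round(fit.se.get("ec50", float("nan")), 6),
            "hill_fit": round(fit.hill, 4),
            "converged": fit.converged,
        }
    dcfg = acfg["densitometry"]
    records = simulate_densitometry(
        dcfg["variant"], fold=float(dcfg["fold"]), cv=float(dcfg["cv"]),
        n_replicates=int(dcfg["n_replicates"]),
        seed=replicate_seed(seed_base, 101, 0, 0),
    )
    contrast = mi_ratio_contrast(records)
    summary["densitometry"] = {
        "variant": dcfg["variant"],
        "fold_true": dcfg["fold"],
        "fold_est": round(contrast["fold"], 4),
        "welch_p": round(contrast["p"], 6),
    }
    return summary


def run_pipeline(config: dict | None = None, out_dir="pipeline_out") -> dict:
    """Run every stage; deterministic given the config's seed.

    Returns the consolidated summary (also written to ``summary.json``).
    On stage failure a :class:`PipelineError` naming the stage is
    raised, and the MANIFEST marks the run incomplete while retaining
    partial outputs.
    """
    config = config if config is not None else default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    summary: dict = {
        "version": __version__,
        "config_hash": cfg_hash,
        "seed": config["seed"],
    }
    completed: list[str] = []

    def _manifest(complete: bool) -> None:
        files = sorted(p.name for p in out.iterdir() if p.name != "MANIFEST")
        with open(out / "MANIFEST", "w") as fh:
            fh.write(f"# config_hash={cfg_hash}\n")
            fh.write(f"# status={'complete' if complete else 'INCOMPLETE'}\n")
            fh.write(f"# stages_completed={','.join(completed)}\n")
            for f in files:
                fh.write(f + "\n")

    try:
        if config["mode"] == "simulate":
            sets = stage_simulate(config, out, cfg_hash)
        else:
            sets = load_simulated(config, out)
        completed.append("simulate")
        stage_fns = [
            ("a100", lambda: stage_a100(config, out, cfg_hash, sets)),
            ("blocking", lambda: stage_blocking(config, out, cfg_hash, sets)),
            ("distances", lambda: stage_distances(config, out, cfg_hash, sets)),
            ("contacts", lambda: stage_contacts(config, out, cfg_hash, sets)),
            ("assay", lambda: stage_assay(config, out, cfg_hash)),
        ]
        for name, fn in stage_fns:
            logger.info("running stage %s", name)
            summary[name] = fn()
            completed.append(name)
    except PipelineError:
        _manifest(False)
        raise
    except Exception as exc:
        failed = STAGES[len(completed)] if len(completed) < len(STAGES) else "report"
        _manifest(False)
        raise PipelineError(failed, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    completed.append("report")
    _manifest(True)
    return summary
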