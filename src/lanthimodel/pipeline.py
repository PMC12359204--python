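"""End-to-end pipeline: sample -> (atropisomer filter) -> fit -> analyze.

A run is driven by one YAML config; unknown keys are rejected so typos
fail before any compute.  Every output file carries a provenance header
(tool version, config hash, seed) and identical config+seed reproduces
identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .analysis import analyze_ensemble
from .atropisomer import filter_pool, parse_probes
from .pdbio import write_ensemble
from .restraints import parse_restraints_tsv, parse_upl
from .sampler import SamplerConfig, SimpleScore, sample_unstructured
from .selection import EnsembleNOEModel, SelectorConfig
from .topology import parse_topology

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


_SAMPLE_KEYS = {"n_models", "burn_in", "production", "top_fraction",
                "small_move_deg", "shear_move_deg", "large_move_deg",
                "mc_temperature", "closure_tol"}
_SELECT_KEYS = {"steps", "size_min", "size_max", "size_init",
                "temperature", "shift_weight", "allow_duplicates", "mode"}
_TOP_KEYS = {"seed", "topology", "restraints", "sample", "select",
             "atropisomer", "output_dir", "verbosity"}
_ATROPO_KEYS = {"probes", "reference"}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    topology_path: str
    restraints_path: str
    output_dir: str
    sample: dict
    select: dict
    atropisomer: dict | None = None

    @classmethod
    def from_dict(cls, raw: dict, base: Path) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("seed", "topology", "restraints", "output_dir"):
            if key not in raw:
                raise PipelineError(f"config missing required key {key!r}")
        sample = dict(raw.get("sample", {}))
        if set(sample) - _SAMPLE_KEYS:
            raise PipelineError(
                f"unknown sample keys: {sorted(set(sample) - _SAMPLE_KEYS)}"
            )
        select = dict(raw.get("select", {}))
        if set(select) - _SELECT_KEYS:
            raise PipelineError(
                f"unknown select keys: {sorted(set(select) - _SELECT_KEYS)}"
            )
        atropo = raw.get("atropisomer")
        if atropo is not None and set(atropo) - _ATROPO_KEYS:
            raise PipelineError(
                f"unknown atropisomer keys: "
                f"{sorted(set(atropo) - _ATROPO_KEYS)}"
            )
        topo = base / raw["topology"]
        restraints = base / raw["restraints"]
        for p in (topo, restraints):
            if not p.exists():
                raise PipelineError(f"input file not found: {p}")
        return cls(int(raw["seed"]), str(topo), str(restraints),
                   str(base / raw["output_dir"]), sample, select, atropo)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise PipelineError("config must be a YAML mapping")
        return cls.from_dict(raw, path.parent)

    def digest(self) -> str:
        blob = json.dumps({
            "seed": self.seed, "sample": self.sample, "select": self.select,
            "atropisomer": self.atropisomer,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [f"lanthimodel {__version__}",
            f"config sha256:{config.digest()}",
            f"seed {config.seed}"]


def _header(config: RunConfig) -> str:
    return "".join(f"# {line}\n" for line in _provenance(config))


def run_pipeline(config: RunConfig, log=None) -> dict[str, Path]:
    """Run all stages, checkpointing each artifact to the output dir.

    Returns the map of artifact names to paths.  Stage failures raise
    :class:`PipelineError` naming the stage.
    """
    def say(msg: str) -> None:
        if log is not None:
            log(msg)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    topology = parse_topology(Path(config.topology_path).read_text())
    rtext = Path(config.restraints_path).read_text()
    if config.restraints_path.endswith(".upl"):
        restraints = parse_upl(rtext, topology)
    else:
        restraints = parse_restraints_tsv(rtext, topology)
    say(f"topology: {len(topology)} residues, {len(topology.rings)} rings; "
        f"{len(restraints)} restraints")

    # stage 1: sampling
    try:
        sampler_cfg = SamplerConfig(seed=config.seed, **config.sample)
        score = SimpleScore()
        pool = sample_unstructured(topology, sampler_cfg, score)
    except Exception as exc:
        raise PipelineError(f"stage 'sample' failed: {exc}") from exc
    scores = [score(c) for c in pool]
    artifacts["pool"] = out / "pool.pdb"
    write_ensemble(pool, artifacts["pool"], remarks=_provenance(config))
    artifacts["pool_scores"] = out / "pool_scores.tsv"
    with open(artifacts["pool_scores"], "w") as fh:
        fh.write(_header(config))
        fh.write("model\tscore\n")
        for i, s in enumerate(scores, start=1):
            fh.write(f"{i}\t{s:.4f}\n")
    say(f"sampled pool of {len(pool)} models")

    # stage 2: optional atropisomer filter
    if config.atropisomer:
        try:
            probes = parse_probes(config.atropisomer["probes"])
            reference = config.atropisomer.get("reference", "majority")
            if reference != "majority":
                reference = tuple(int(x) for x in str(reference).split(","))
            pool, census = filter_pool(pool, probes, reference)
            scores = None  # stale after filtering; recompute below
        except Exception as exc:
            raise PipelineError(
                f"stage 'atropisomer' failed: {exc}") from exc
        artifacts["census"] = out / "atropisomer_census.tsv"
        with open(artifacts["census"], "w") as fh:
            fh.write(_header(config))
            fh.write("key\tcount\n")
            for key, count in sorted(census.items()):
                fh.write(f"{','.join(map(str, key))}\t{count}\n")
        artifacts["filtered_pool"] = out / "pool_filtered.pdb"
        write_ensemble(pool, artifacts["filtered_pool"],
                       remarks=_provenance(config))
        say(f"atropisomer filter kept {len(pool)} models "
            f"({len(census)} classes)")
    if scores is None:
        scores = [SimpleScore()(c) for c in pool]

    # stage 3: ensemble selection
    try:
        select_kwargs = dict(config.select)
        mode = select_kwargs.pop("mode", "kind_aware")
        sel_cfg = SelectorConfig(seed=config.seed, **select_kwargs)
        model = EnsembleNOEModel(pool, restraints, mode=mode)
        results = model.fit(sel_cfg, trace_every=max(1, sel_cfg.steps // 200))
    except Exception as exc:
        raise PipelineError(f"stage 'fit-ensemble' failed: {exc}") from exc
    artifacts["ensemble"] = out / "ensemble.pdb"
    write_ensemble(results.members, artifacts["ensemble"],
                   remarks=_provenance(config))
    artifacts["restraint_report"] = out / "restraint_report.tsv"
    with open(artifacts["restraint_report"], "w") as fh:
        fh.write(_header(config))
        results.restraint_table().to_csv(fh, sep="\t", index=False)
    artifacts["trajectory"] = out / "trajectory.tsv"
    with open(artifacts["trajectory"], "w") as fh:
        fh.write(_header(config))
        fh.write("step\tscore\tbest_score\tsize\n")
        for step, cur, best, size in results.trace:
            fh.write(f"{step}\t{cur:.6f}\t{best:.6f}\t{size}\n")
    say(f"selected ensemble of {results.state.size}, "
        f"score {results.score:.4f}")

    # stage 4: analysis
    try:
        member_scores = [scores[i] for i in results.state.indices]
        members_df, residues_df = analyze_ensemble(
            results.members, "lowest_score", member_scores)
    except Exception as exc:
        raise PipelineError(f"stage 'analyze' failed: {exc}") from exc
    artifacts["analysis_members"] = out / "analysis_members.tsv"
    artifacts["analysis_residues"] = out / "analysis_residues.tsv"
    for name, df in (("analysis_members", members_df),
                     ("analysis_residues", residues_df)):
        with open(artifacts[name], "w") as fh:
            fh.write(_header(config))
            df.to_csv(fh, sep="\t", index=False)
    say("analysis written")
    return artifacts
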