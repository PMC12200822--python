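"""Configured end-to-end runs: load/simulate -> learn -> fit -> recommend.

A run is described by a YAML/dict config, validated before any compute and
echoed into every artifact for provenance.  Outputs are deterministic under
a fixed config and seed.  Convergence failure downgrades the run with a
prominent warning in the log and the convergence artifact — it does not
abort — while schema errors always abort.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .decision import SUBUTILITY_PRESETS, UtilitySpec, sensitivity_table
from .domains import DEFAULT_DOMAINS, DomainRegistry, ProfileState
from .estimators import InterventionRecommender
from .panel import read_panel_csv, write_panel_csv
from .synthetic import GeneratorConfig, sample_scm, simulate_panel

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_KNOWN_KEYS = {
    "panel",
    "simulate",
    "domains",
    "mcmc",
    "pseudocount",
    "utilities",
    "top_n",
    "n_networks",
    "consensus_threshold",
    "seed",
    "baseline",
    "edge_whitelist",
    "out_dir",
}

_KNOWN_MCMC_KEYS = {
    "chains",
    "iterations",
    "burn_in",
    "thin",
    "max_parents",
    "alpha_mu",
    "alpha_w",
    "convergence_tolerance",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: str
    panel: str | None = None
    simulate: dict | None = None
    domains: tuple[str, ...] = DEFAULT_DOMAINS
    mcmc: dict = field(default_factory=dict)
    pseudocount: float = 1.0
    utilities: tuple[str, ...] = ("default", "risk_neutral", "risk_averse")
    top_n: int = 3
    n_networks: int = 200
    consensus_threshold: float = 0.10
    seed: int = 1
    baseline: dict | None = None
    edge_whitelist: list | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise PipelineError(f"stage config: unknown keys {sorted(unknown)}")
        if "out_dir" not in raw:
            raise PipelineError("stage config: 'out_dir' is required")
        if (raw.get("panel") is None) == (raw.get("simulate") is None):
            raise PipelineError(
                "stage config: exactly one of 'panel' and 'simulate' is required"
            )
        mcmc = dict(raw.get("mcmc") or {})
        unknown_mcmc = set(mcmc) - _KNOWN_MCMC_KEYS
        if unknown_mcmc:
            raise PipelineError(
                f"stage config: unknown mcmc keys {sorted(unknown_mcmc)}"
            )
        domains = tuple(raw.get("domains") or DEFAULT_DOMAINS)
        for name in raw.get("utilities", []):
            if name not in SUBUTILITY_PRESETS:
                raise PipelineError(
                    f"stage config: unknown utility preset {name!r}"
                )
        cfg = cls(
            out_dir=str(raw["out_dir"]),
            panel=raw.get("panel"),
            simulate=raw.get("simulate"),
            domains=domains,
            mcmc=mcmc,
            pseudocount=float(raw.get("pseudocount", 1.0)),
            utilities=tuple(raw.get("utilities", cls.utilities)),
            top_n=int(raw.get("top_n", 3)),
            n_networks=int(raw.get("n_networks", 200)),
            consensus_threshold=float(raw.get("consensus_threshold", 0.10)),
            seed=int(raw.get("seed", 1)),
            baseline=raw.get("baseline"),
            edge_whitelist=raw.get("edge_whitelist"),
        )
        cfg._validate_whitelist()
        return cfg

    def _validate_whitelist(self) -> None:
        if not self.edge_whitelist:
            return
        k = len(self.domains)
        names = [f"{d}_t0" for d in self.domains] + [
            f"{d}_t1" for d in self.domains
        ]
        for entry in self.edge_whitelist:
            if len(entry) != 2 or entry[0] not in names or entry[1] not in names:
                raise PipelineError(
                    f"stage config: malformed edge_whitelist entry {entry!r}"
                )
            u, v = names.index(entry[0]), names.index(entry[1])
            if u >= k and v < k:
                raise PipelineError(
                    f"stage config: edge_whitelist entry {entry!r} goes "
                    "backwards in time (follow-up -> baseline)"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PipelineError("stage config: config file must be a mapping")
        return cls.from_dict(raw)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the populated run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    echo = asdict(config)
    _dump_json(echo, out / "config.json")
    log(f"config: seed={config.seed} out_dir={config.out_dir}")

    registry = DomainRegistry(config.domains)
    try:
        if config.panel is not None:
            panel = read_panel_csv(config.panel, registry)
            log(f"load: read {panel.n} records from {config.panel}")
        else:
            sim = dict(config.simulate)
            n = int(sim.pop("n"))
            gen_seed = int(sim.pop("seed", config.seed))
            gen = GeneratorConfig(registry=registry, seed=gen_seed, **sim)
            truth = sample_scm(gen)
            panel = simulate_panel(truth, n, seed=gen_seed + 1)
            write_panel_csv(panel, out / "panel.csv")
            _dump_json(truth.bn.to_dict(), out / "ground_truth_bn.json")
            log(f"simulate: generated {n} records (generator seed {gen_seed})")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage load/simulate: {exc}") from exc

    if config.edge_whitelist:
        log(
            "warning: edge_whitelist is validated but not used as a structure "
            "prior; only the temporal constraint shapes the prior"
        )

    try:
        rec = InterventionRecommender(
            n_chains=int(config.mcmc.get("chains", 8)),
            n_iterations=int(config.mcmc.get("iterations", 60_000)),
            burn_in=int(config.mcmc.get("burn_in", 20_000)),
            thin=int(config.mcmc.get("thin", 40)),
            max_parents=config.mcmc.get("max_parents", 4),
            alpha_mu=float(config.mcmc.get("alpha_mu", 1.0)),
            alpha_w=config.mcmc.get("alpha_w"),
            pseudocount=config.pseudocount,
            top_n=config.top_n,
            n_networks=config.n_networks,
            consensus_threshold=config.consensus_threshold,
            random_state=config.seed,
        )
        rec.fit(panel)
    except Exception as exc:
        raise PipelineError(f"stage learn: {exc}") from exc

    samples = rec.samples_
    _dump_json({"config": echo, **samples.to_dict()}, out / "samples.json")
    log(
        "learn: "
        f"{len(samples)} draws over {samples.n_chains} chains; "
        f"acceptance rates {[round(r, 3) for r in samples.acceptance_rates]}"
    )
    log(f"learn: chain seeds {samples.seeds}")

    conv = getattr(rec.structure_, "convergence_", None)
    if conv is not None:
        _dump_json(
            {
                "max_spread": conv.max_spread,
                "tolerance": conv.tolerance,
                "passed": bool(conv.passed),
            },
            out / "convergence.json",
        )
        if conv.passed:
            log(f"convergence: max edge-probability spread {conv.max_spread:.4f} (pass)")
        else:
            log(
                "WARNING convergence FAILED: max edge-probability spread "
                f"{conv.max_spread:.4f} exceeds {conv.tolerance}; downstream "
                "summaries may be unreliable"
            )

    try:
        edges = rec.consensus_.edges()
        lines = ["parent\tchild\tp_parent\tp_path\tkind"]
        for e in edges:
            lines.append(
                f"{e['parent']}\t{e['child']}\t{e['p_parent']:.6f}"
                f"\t{e['p_path']:.6f}\t{e['kind']}"
            )
        (out / "consensus_edges.tsv").write_text("\n".join(lines) + "\n")
        dot = ["digraph consensus {"]
        for e in edges:
            style = "dashed" if e["kind"] in ("lagged", "autoregressive") else "solid"
            dot.append(
                f'  "{e["parent"]}" -> "{e["child"]}" '
                f'[label="{e["p_parent"]:.2f}", style={style}];'
            )
        dot.append("}")
        (out / "consensus.dot").write_text("\n".join(dot) + "\n")
        log(f"consensus: {len(edges)} edges above threshold {config.consensus_threshold}")
    except Exception as exc:
        raise PipelineError(f"stage consensus: {exc}") from exc

    try:
        specs = [UtilitySpec.preset(name) for name in config.utilities]
        table = sensitivity_table(
            rec.networks_, rec.baseline_weights_, specs, config.top_n
        )
        table.to_csv(out / "sensitivity.tsv", sep="\t")
        report: dict = {"config": echo, "p_opt": {}, "p_rec": {}}
        for spec in specs:
            summary = rec.summarize(spec=spec)
            report["p_opt"][spec.name] = summary.p_opt
            report["p_rec"][spec.name] = summary.p_rec
        if config.baseline is not None:
            state = ProfileState.from_labels(registry, config.baseline)
            result = rec.rank(state)
            report["baseline_report"] = {
                "baseline": state.labels(),
                "eu": dict(result.eu),
                "se": dict(result.se),
                "ate": dict(result.ate),
                "eu_domains": dict(result.eu_domains),
                "ranking": list(result.ranking),
            }
        _dump_json(report, out / "recommendations.json")
        log(f"recommend: utility specs {list(config.utilities)}, top_n={config.top_n}")
    except Exception as exc:
        raise PipelineError(f"stage recommend: {exc}") from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
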