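"""Configuration, presets, fixtures and serialization glue.

A :class:`RunConfig` fully describes one simulation run (model selector,
parameter block, forcing, integration and output settings, master seed)
and round-trips losslessly through YAML/TOML.  Presets reproduce the
standard experiment configurations at full scale, with a ``ci_scale``
override that shrinks network sizes and time spans for quick runs.

Seeding: one master seed deterministically spawns sub-seeds for
currents, connectivity and initial conditions, so an amplitude sweep can
freeze the connectivity sub-seed while the rest of the run varies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

MODELS = ("cell", "dense", "sparse", "meanfield", "heuristic-meanfield", "multipop")

_SECTION_KEYS = {
    "params": {
        "eta", "eta_bar", "delta", "j_syn", "tau_s", "gamma_coupling",
        "g_elec", "a_spike", "n_neurons", "m_links", "degree_hwhm_coeff",
        "v_threshold", "v_reset", "increment_convention", "spike_increment",
    },
    "forcing": {"amplitude", "epsilon"},
    "integration": {"dt", "rtol", "atol", "t_span", "burn_in", "estimator",
                    "window_dt"},
    "output": {"dir", "formats", "prefix"},
}

_DEFAULTS = {
    "integration": {"dt": 1e-4, "estimator": "median"},
    "output": {"formats": ["csv", "json"]},
}


@dataclass
class RunConfig:
    """Validated configuration of a single run."""

    model: str
    params: dict = field(default_factory=dict)
    forcing: dict = field(default_factory=dict)
    integration: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        for section in ("params", "forcing", "integration", "output"):
            block = getattr(self, section)
            unknown = set(block) - _SECTION_KEYS[section]
            if unknown:
                raise ValueError(
                    f"unknown key(s) in [{section}]: {sorted(unknown)}"
                )
        for section, defaults in _DEFAULTS.items():
            block = getattr(self, section)
            for k, v in defaults.items():
                block.setdefault(k, v)

    # -- (de)serialisation ---------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {"model", "params", "forcing", "integration", "output", "seed"}
        if unknown:
            raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
        if "model" not in d:
            raise ValueError("config must name a model")
        return cls(
            model=d["model"],
            params=dict(d.get("params", {})),
            forcing=dict(d.get("forcing", {})),
            integration=dict(d.get("integration", {})),
            output=dict(d.get("output", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def subseed(self, stream: str) -> int:
        """Deterministic sub-seed for a named random stream.

        Streams: "currents", "connectivity", "init", ... .  Derived by
        hashing (master seed, stream name) so freezing one stream while
        sweeping parameters is just reusing its name.
        """
        h = hashlib.sha256(f"{self.seed}:{stream}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or TOML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        data = tomllib.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# presets: the standard experiment configurations
# ---------------------------------------------------------------------------

PRESET_TABLE: dict[str, dict] = {
    # single bistable cell, slow forcing, threshold bracket [0.20318, 0.20319]
    "fig1": {
        "model": "cell",
        "params": {"eta": -0.2, "j_syn": 6.0, "tau_s": 0.3, "spike_increment": 1.0},
        "forcing": {"amplitude": 0.20319, "epsilon": 0.01},
        "integration": {"t_span": [0.0, 377.0]},
    },
    # single tonic cell, measured on t in [0, 70]
    "fig2": {
        "model": "cell",
        "params": {"eta": 0.5, "j_syn": 6.0, "tau_s": 0.3, "spike_increment": 1.0},
        "forcing": {"amplitude": 0.8892, "epsilon": 0.1},
        "integration": {"t_span": [0.0, 70.0]},
    },
    # mean field, bistable regime
    "fig4": {
        "model": "meanfield",
        "params": {"delta": 1.0, "j_syn": 15.0, "tau_s": 0.002, "eta_bar": -15.1},
        "forcing": {"amplitude": 12.1131, "epsilon": 0.05},
        "integration": {"t_span": [0.0, 126.0], "rtol": 1e-8, "atol": 1e-10},
    },
    # dense network mirroring fig4
    "fig5": {
        "model": "dense",
        "params": {
            "n_neurons": 100_000, "delta": 1.0, "j_syn": 15.0, "tau_s": 0.002,
            "eta_bar": -15.1, "v_threshold": 100.0, "v_reset": -100.0,
            "increment_convention": "one_over_N_tau",
        },
        "forcing": {"amplitude": 12.1131, "epsilon": 0.05},
        "integration": {"t_span": [0.0, 70.0], "dt": 1e-4},
    },
    # sparse network (coefficient units; sqrt(M) scaling profile)
    "fig7": {
        "model": "sparse",
        "params": {
            "n_neurons": 10_000, "m_links": 1000, "j_syn": 1.0, "tau_s": 0.015,
            "degree_hwhm_coeff": 0.3, "eta_bar": -0.5, "delta": 1e-4,
            "v_threshold": 100.0, "v_reset": -100.0,
        },
        "forcing": {"amplitude": 0.5031, "epsilon": 0.1},
        "integration": {"t_span": [0.0, 47.0], "dt": 1e-4},
    },
}
for _reg, _eta in (("I", -6.5), ("II", -5.0), ("III", -3.5), ("IV", -2.0)):
    PRESET_TABLE[f"fig6-region{_reg}"] = {
        "model": "meanfield",
        "params": {"delta": 1.0, "j_syn": 15.0, "tau_s": 0.02, "eta_bar": _eta},
        "forcing": {"amplitude": 0.5, "epsilon": 0.05},
        "integration": {"t_span": [0.0, 252.0], "rtol": 1e-8, "atol": 1e-10},
    }


def preset(name: str, overrides: dict | None = None, seed: int = 0) -> RunConfig:
    """Build the RunConfig for a named preset, with optional overrides.

    Overrides are (section, key) -> value mappings, e.g.
    ``{"forcing": {"amplitude": 0.5}}``.
    """
    if name not in PRESET_TABLE:
        raise KeyError(
            f"unknown preset {name!r}; known: {sorted(PRESET_TABLE)}"
        )
    base = json.loads(json.dumps(PRESET_TABLE[name]))  # deep copy
    for section, kv in (overrides or {}).items():
        if section in ("model", "seed"):
            raise ValueError("override sections are params/forcing/integration/output")
        base.setdefault(section, {}).update(kv)
    base["seed"] = seed
    return RunConfig.from_dict(base)


def _ci_scaled(cfg: RunConfig) -> RunConfig:
    d = cfg.to_dict()
    if "n_neurons" in d["params"]:
        d["params"]["n_neurons"] = min(d["params"]["n_neurons"], 500)
    if "m_links" in d["params"]:
        d["params"]["m_links"] = min(
            d["params"]["m_links"], max(1, d["params"]["n_neurons"] // 10)
        )
    if "dt" in d["integration"]:
        d["integration"]["dt"] = max(d["integration"]["dt"], 5e-4)
    t0, t1 = d["integration"].get("t_span", (0.0, 10.0))
    d["integration"]["t_span"] = [t0, t0 + min(t1 - t0, 40.0)]
    return RunConfig.from_dict(d)


def run_preset(
    name: str,
    overrides: dict | None = None,
    ci_scale: bool = False,
    outdir=None,
    seed: int = 0,
) -> dict:
    """Execute a preset end to end, writing traces/spikes and a summary.

    Returns a dict with the written artifact paths and the run summary
    (orbit classification where applicable).  ``ci_scale`` shrinks
    network size and time span for smoke runs.
    """
    from .params import MeanFieldParams, SlowForcing
    from . import experiments as ex
    from .geometry import CriticalManifold
    from .microscale import NetworkParams, simulate_dense_network, simulate_theta_cell
    from .routes import classify_orbit
    from .sparse import SparseParams, build_connectivity, sample_degrees, simulate_sparse_network

    cfg = preset(name, overrides, seed)
    if ci_scale:
        cfg = _ci_scaled(cfg)
    outdir = Path(outdir) if outdir is not None else Path(".")
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = cfg.output.get("prefix", name)
    arts: dict = {"config": str(outdir / f"{prefix}.config.yaml")}
    cfg.dump(arts["config"])
    p, f, integ = cfg.params, cfg.forcing, cfg.integration
    forcing = SlowForcing(f["amplitude"], f["epsilon"])
    t_span = tuple(integ["t_span"])
    summary: dict = {"preset": name, "seed": cfg.seed, "ci_scale": ci_scale}

    if cfg.model == "cell":
        rec, trace = simulate_theta_cell(
            p["eta"], p["j_syn"], p["tau_s"], forcing, t_span,
            theta0=0.0, s0=0.0,
            spike_increment=p.get("spike_increment", 1.0), record=True,
        )
        spath = outdir / f"{prefix}.spikes.tsv"
        rec.write_tsv(spath)
        arts["spikes"] = str(spath)
        summary["n_spikes"] = len(rec)
    elif cfg.model == "meanfield":
        mf = MeanFieldParams(
            delta=p["delta"], j_syn=p["j_syn"], eta_bar=p["eta_bar"], tau_s=p["tau_s"]
        )
        man = CriticalManifold(mf)
        sheet = "lower" if mf.eta_bar < man.folds()[1].eta_fold else "upper"
        traj = ex.meanfield_orbit(
            mf, forcing.amplitude, forcing.epsilon, start_sheet=sheet,
            n_periods=(t_span[1] - t_span[0]) / forcing.period,
        )
        tpath = outdir / f"{prefix}.trajectory.csv"
        traj.write_csv(tpath)
        arts["trajectory"] = str(tpath)
        if t_span[1] - t_span[0] >= 2 * forcing.period - 1e-9:
            summary["orbit_class"] = classify_orbit(traj, man, forcing.period).value
        else:
            summary["orbit_class"] = classify_orbit(
                traj, man, min(forcing.period, t_span[1]), transient=0.0
            ).value
    elif cfg.model == "dense":
        net = NetworkParams(
            n_neurons=int(p["n_neurons"]), j_syn=p["j_syn"], tau_s=p["tau_s"],
            eta_bar=p["eta_bar"], delta=p["delta"],
            seed=cfg.subseed("currents"),
            v_threshold=p.get("v_threshold", 100.0),
            v_reset=p.get("v_reset", -100.0), dt=integ["dt"],
            increment_convention=p.get("increment_convention", "one_over_N_tau"),
        )
        mf = MeanFieldParams(
            delta=p["delta"], j_syn=p["j_syn"], eta_bar=p["eta_bar"], tau_s=p["tau_s"]
        )
        man = CriticalManifold(mf)
        v0 = man.branch_voltage(mf.eta_bar, "lower")
        r0 = float(man.rate(v0))
        rec, trace = simulate_dense_network(
            net, forcing, (v0, r0), t_span,
            window_dt=integ.get("window_dt", 0.15),
            estimator=integ["estimator"],
        )
        spath = outdir / f"{prefix}.spikes.tsv"
        tpath = outdir / f"{prefix}.trace.csv"
        rec.write_tsv(spath)
        trace.write_csv(tpath)
        arts.update(spikes=str(spath), trace=str(tpath))
        traj = ex.trajectory_from_trace(
            trace.times, trace.mean_v, trace.inst_rate, trace.mean_s,
            mf.eta_bar, forcing,
        )
        summary["orbit_class"] = classify_orbit(
            traj, man, min(forcing.period, t_span[1] - t_span[0]), transient=0.0
        ).value
        summary["n_spikes"] = len(rec)
    elif cfg.model == "sparse":
        sp = SparseParams(
            n_neurons=int(p["n_neurons"]), m_links=int(p["m_links"]),
            j_syn=p["j_syn"], degree_hwhm_coeff=p["degree_hwhm_coeff"],
            eta_bar=p["eta_bar"], delta=p["delta"], tau_s=p["tau_s"],
            amp_coeff=f["amplitude"], epsilon=f["epsilon"],
            seed=cfg.subseed("currents"), dt=integ["dt"],
        )
        degrees = sample_degrees(
            sp.m_links, sp.degree_hwhm_coeff, sp.n_neurons,
            cfg.subseed("connectivity"),
        )
        conn = build_connectivity(degrees, sp.n_neurons, cfg.subseed("connectivity"))
        rec, trace = simulate_sparse_network(sp, conn, (0.0, 0.0), t_span)
        spath = outdir / f"{prefix}.spikes.tsv"
        tpath = outdir / f"{prefix}.trace.csv"
        rec.write_tsv(spath)
        trace.write_csv(tpath)
        arts.update(spikes=str(spath), trace=str(tpath))
        summary["n_spikes"] = len(rec)
    else:
        raise ValueError(f"preset runner not implemented for model {cfg.model!r}")

    from . import __version__

    summary["version"] = __version__
    summary["checksums"] = {
        k: hashlib.sha256(Path(v).read_bytes()).hexdigest()[:16]
        for k, v in arts.items()
    }
    sp = outdir / f"{prefix}.summary.json"
    sp.write_text(json.dumps(summary, indent=2))
    arts["summary"] = str(sp)
    return {"artifacts": arts, "summary": summary}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(seed: int, outdir) -> dict:
    """Write the small deterministic inputs used by the test suite.

    A 50-neuron Lorentzian current draw, a 100x100 sparse adjacency with
    Cauchy degrees, and a short mean-field trajectory; a checksum
    manifest makes regressions visible.
    """
    from .microscale import sample_lorentzian
    from .params import MeanFieldParams
    from .sparse import build_connectivity, sample_degrees

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(model="meanfield", seed=seed)

    currents = sample_lorentzian(-15.1, 1.0, 50, cfg.subseed("currents"))
    cpath = outdir / "currents.csv"
    np.savetxt(cpath, currents, header="eta", comments="")

    degrees = sample_degrees(20, 0.3, 100, cfg.subseed("connectivity"))
    conn = build_connectivity(degrees, 100, cfg.subseed("connectivity"))
    apath = outdir / "adjacency.txt"
    conn.write(apath)

    mf = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=0.02)
    from . import experiments as ex

    traj = ex.meanfield_orbit(mf, 5.0, 0.05, n_periods=0.2, n_eval=200)
    tpath = outdir / "trajectory.csv"
    traj.write_csv(tpath, sidecar=False)

    checks = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in (cpath, apath, tpath)
    }
    (outdir / "checksums.json").write_text(json.dumps(checks, indent=2))
    return {"dir": str(outdir), "checksums": checks, "degrees": degrees}
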