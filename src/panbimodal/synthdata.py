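"""Synthetic multi-layer cell-line data with planted bimodal switches.

Generative model: each switch module carries one shared Bernoulli(pi_high)
latent state per cell; every member analyte copies that state with
probability ``coupling_rho`` and flips it otherwise.  Values are drawn from
N(mu_low, sigma^2) or N(mu_low + delta_mu*sigma, sigma^2) given the
analyte-level state.  Missingness is completely at random per layer.

A separate linear-Gaussian SEM generator provides known-DAG data for the
causal module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import Annotation, ExpressionMatrix, VALID_LAYERS, write_matrix


@dataclass
class SwitchSpec:
    """Parameters of one planted bimodal switch module."""

    id: str
    layers: tuple[str, ...] = ("protein",)
    pi_high: float = 0.5
    delta_mu: float = 4.0
    sigma: float = 1.0
    coupling_rho: float = 1.0
    mu_low: float = 0.0
    tissue_bias: dict[str, float] | None = None
    n_analytes_per_layer: int = 1
    sigma_high: float | None = None  # unequal-SD option; defaults to sigma

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_high < 1.0:
            raise ValueError(f"switch {self.id}: pi_high must be in (0,1)")
        if self.delta_mu < 0:
            raise ValueError(f"switch {self.id}: delta_mu must be >= 0")
        if self.sigma <= 0:
            raise ValueError(f"switch {self.id}: sigma must be > 0")
        if not 0.5 <= self.coupling_rho <= 1.0:
            raise ValueError(f"switch {self.id}: coupling_rho must be in [0.5, 1]")
        bad = [l for l in self.layers if l not in VALID_LAYERS]
        if bad:
            raise ValueError(f"switch {self.id}: unknown layers {bad}")

    @property
    def mu_high(self) -> float:
        return self.mu_low + self.delta_mu * self.sigma

    @property
    def is_bimodal(self) -> bool:
        return self.delta_mu > 0


@dataclass
class SimulatedDataset:
    """Multi-layer matrices plus the planted ground truth."""

    matrices: dict[str, ExpressionMatrix]
    annotations: Annotation
    truth: dict
    seed: int

    @property
    def cell_ids(self) -> list[str]:
        return next(iter(self.matrices.values())).cell_ids

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for layer, m in self.matrices.items():
            write_matrix(m, outdir / f"{layer}.tsv")
        ann = self.annotations.table.copy()
        ann.index.name = "cell_line"
        ann.to_csv(outdir / "annotations.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def simulate_multilayer(
    n_cells: int,
    tissues: Sequence[tuple[str, int]],
    switches: Sequence[SwitchSpec],
    n_unimodal: int = 0,
    missing_rate: float | dict[str, float] = 0.0,
    seed: int = 0,
    unimodal_layers: tuple[str, ...] = ("protein",),
) -> SimulatedDataset:
    """Generate a planted-truth multi-layer dataset.

    ``tissues`` is a list of (name, size) pairs whose sizes must sum to
    ``n_cells``.  ``missing_rate`` applies per layer (scalar or per-layer map)
    and must be < 1.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not tissues:
        raise ValueError("tissue list must be non-empty")
    sizes = [int(s) for _, s in tissues]
    if sum(sizes) != n_cells:
        raise ValueError(f"tissue sizes sum to {sum(sizes)}, expected n_cells={n_cells}")
    rates = missing_rate if isinstance(missing_rate, dict) else {
        l: float(missing_rate) for l in VALID_LAYERS}
    for l, r in rates.items():
        if not 0.0 <= r < 1.0:
            raise ValueError(f"missing_rate for layer {l} must be in [0,1), got {r}")

    rng = np.random.default_rng(seed)
    cell_ids = [f"CL{i:04d}" for i in range(n_cells)]
    tissue_labels = np.concatenate([np.full(s, name) for name, s in tissues])

    layer_rows: dict[str, dict[str, np.ndarray]] = {l: {} for l in VALID_LAYERS}
    truth_states: dict[str, list[int]] = {}
    truth_bimodal: dict[str, bool] = {}
    truth_module: dict[str, str] = {}
    analyte_states: dict[str, list[int]] = {}

    for sw in switches:
        if sw.tissue_bias:
            p_high = np.array([sw.tissue_bias.get(t, sw.pi_high) for t in tissue_labels])
        else:
            p_high = np.full(n_cells, sw.pi_high)
        module_state = (rng.random(n_cells) < p_high).astype(int)
        truth_states[sw.id] = module_state.tolist()
        sig_hi = sw.sigma if sw.sigma_high is None else sw.sigma_high
        for layer in sw.layers:
            for k in range(sw.n_analytes_per_layer):
                name = sw.id if (len(sw.layers) == 1 and sw.n_analytes_per_layer == 1) \
                    else f"{sw.id}.{layer}.{k}"
                agree = rng.random(n_cells) < sw.coupling_rho
                state = np.where(agree, module_state, 1 - module_state)
                noise = rng.standard_normal(n_cells)
                vals = np.where(
                    state == 1,
                    sw.mu_high + sig_hi * noise,
                    sw.mu_low + sw.sigma * noise,
                )
                layer_rows[layer][name] = vals
                truth_bimodal[name] = sw.is_bimodal
                truth_module[name] = sw.id
                analyte_states[name] = state.tolist()

    for k in range(n_unimodal):
        name = f"uni{k:04d}"
        for layer in unimodal_layers:
            rname = name if len(unimodal_layers) == 1 else f"{name}.{layer}"
            layer_rows[layer][rname] = rng.standard_normal(n_cells)
            truth_bimodal[rname] = False

    matrices: dict[str, ExpressionMatrix] = {}
    for layer, rows in layer_rows.items():
        if not rows:
            continue
        df = pd.DataFrame(rows, index=cell_ids).T
        r = rates.get(layer, 0.0)
        if r > 0:
            mask = rng.random(df.shape) < r
            df = df.mask(mask)
        matrices[layer] = ExpressionMatrix(layer=layer, values=df)

    tumor_class = rng.choice(["primary", "metastasis"], size=n_cells)
    ann = Annotation(pd.DataFrame(
        {"tissue": tissue_labels, "tumor_class": tumor_class},
        index=pd.Index(cell_ids, name="cell_line")))

    truth = {
        "module_state": truth_states,
        "analyte_state": analyte_states,
        "is_bimodal": truth_bimodal,
        "module_of": truth_module,
        "switches": {sw.id: {
            "pi_high": sw.pi_high, "delta_mu": sw.delta_mu, "sigma": sw.sigma,
            "coupling_rho": sw.coupling_rho, "mu_low": sw.mu_low,
            "mu_high": sw.mu_high, "layers": list(sw.layers),
        } for sw in switches},
        "seed": seed,
    }
    return SimulatedDataset(matrices=matrices, annotations=ann, truth=truth, seed=seed)


def simulate_sem(
    dag: Sequence[tuple[str, str, float]],
    n_samples: int,
    noise_sd: float | dict[str, float] = 1.0,
    seed: int = 0,
    extra_nodes: Sequence[str] = (),
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Sample a linear-Gaussian SEM: each node = sum(weight * parent) + noise.

    ``dag`` is an edge list ``(parent, child, weight)`` and must be acyclic.
    Returns the samples (n_samples x nodes) and the truth DAG edge list.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    nodes: list[str] = []
    for u, v, _ in dag:
        for x in (u, v):
            if x not in nodes:
                nodes.append(x)
    for x in extra_nodes:
        if x not in nodes:
            nodes.append(x)
    if not nodes:
        raise ValueError("empty SEM: provide edges or extra_nodes")

    parents: dict[str, list[tuple[str, float]]] = {n: [] for n in nodes}
    for u, v, w in dag:
        parents[v].append((u, float(w)))

    order: list[str] = []
    temp, perm = set(), set()

    def visit(n: str) -> None:
        if n in perm:
            return
        if n in temp:
            raise ValueError("dag contains a cycle")
        temp.add(n)
        for p, _ in parents[n]:
            visit(p)
        temp.discard(n)
        perm.add(n)
        order.append(n)

    for n in nodes:
        visit(n)

    sds = noise_sd if isinstance(noise_sd, dict) else {n: float(noise_sd) for n in nodes}
    for n, sd in sds.items():
        if sd <= 0:
            raise ValueError(f"noise_sd for {n} must be > 0")

    rng = np.random.default_rng(seed)
    data = {n: None for n in nodes}
    for n in order:
        x = rng.standard_normal(n_samples) * sds.get(n, 1.0)
        for p, w in parents[n]:
            x = x + w * data[p]
        data[n] = x
    df = pd.DataFrame({n: data[n] for n in nodes})
    return df, [(u, v, float(w)) for u, v, w in dag]


def scenario_from_yaml(cfg: dict) -> dict:
    """Normalize a YAML scenario mapping into simulate_multilayer kwargs."""
    switches = [SwitchSpec(
        id=s["id"],
        layers=tuple(s.get("layers", ["protein"])),
        pi_high=float(s.get("pi_high", 0.5)),
        delta_mu=float(s.get("delta_mu", 4.0)),
        sigma=float(s.get("sigma", 1.0)),
        coupling_rho=float(s.get("coupling_rho", 1.0)),
        mu_low=float(s.get("mu_low", 0.0)),
        tissue_bias=s.get("tissue_bias"),
        n_analytes_per_layer=int(s.get("n_analytes_per_layer", 1)),
    ) for s in cfg.get("switches", [])]
    return dict(
        n_cells=int(cfg["n_cells"]),
        tissues=[(t["name"], int(t["size"])) for t in cfg["tissues"]],
        switches=switches,
        n_unimodal=int(cfg.get("n_unimodal", 0)),
        missing_rate=cfg.get("missing_rate", 0.0),
    )
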