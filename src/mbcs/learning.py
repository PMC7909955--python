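"""Shared vs modality-segregated Kenyon-cell populations in a learning model.

The simulation asks when it pays to dedicate separate KC subpopulations to
separate sensory modalities.  Stimuli are pairs of random binary patterns
(one olfactory, one visual component).  In the *factorizable* task each
component pattern carries its own subvalence (positive or neutral) and the
net valence is a fixed combination of the two (OR by default: positive if
either component is positive; AND is also available).  In the
*unfactorizable* task every component pair gets an independent random
valence, so the label is not a function of the components separately.

Stimuli are all combinations of small per-modality component pools (by
default 20×10 = 200 factorizable stimuli and 5×5 = 25 unfactorizable ones),
which keeps the two tasks comparable in difficulty.

KCs sample a fixed number of claws from their allowed PN pool — both
modalities in the *shared* architecture, a single modality for each half of
the population in the *separate* architecture — and fire sparsely: a global
threshold is calibrated so a fraction f of KCs is active per stimulus.  A
ridge-regularised linear readout (the model MBON; the fit stands in for
experience-driven KC→MBON plasticity) is trained on ±1 valences, either as
one fit on the whole population (*shared reward signal*) or as per-modality
fits against the per-modality subvalences whose outputs converge additively
(*separate reward signals*).  Performance is the binary accuracy of the
thresholded readout on the presented stimuli.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

logger = logging.getLogger("mbcs")

MODALITY_NAMES = ("olfactory", "visual")


# ---------------------------------------------------------------------------
# tasks
# ---------------------------------------------------------------------------

def _component_pool_sizes(n_stimuli: int) -> tuple[int, int]:
    """Split n_stimuli into the most square factor pair (n_olf >= n_vis)."""
    best = (n_stimuli, 1)
    for a in range(1, int(np.sqrt(n_stimuli)) + 1):
        if n_stimuli % a == 0:
            best = (n_stimuli // a, a)
    return best


@dataclass(frozen=True)
class TaskConfig:
    """A valence-discrimination task over two-modality stimuli.

    ``n_stimuli`` defaults follow the simulation conditions: 200 for the
    factorizable task and 25 for the unfactorizable one.  ``combination_rule``
    applies only to the factorizable task: "OR" makes the net valence
    positive when either subvalence is positive, "AND" only when both are.
    """

    factorizable: bool = True
    n_stimuli: int | None = None
    dim_per_modality: int = 50
    pattern_density: float = 0.5
    combination_rule: str = "OR"
    max_resample: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.n_stimuli is None:
            object.__setattr__(self, "n_stimuli", 200 if self.factorizable else 25)
        if self.n_stimuli < 2:
            raise ValueError("need at least two stimuli")
        if self.combination_rule not in ("OR", "AND"):
            raise ValueError("combination_rule must be 'OR' or 'AND'")


@dataclass
class Task:
    x_olf: np.ndarray        # (n_stimuli, dim) binary
    x_vis: np.ndarray
    valence: np.ndarray      # ±1
    sub_olf: np.ndarray      # ±1 per stimulus (+1 positive, −1 neutral)
    sub_vis: np.ndarray
    factorizable: bool

    @property
    def n_stimuli(self) -> int:
        return len(self.valence)


def generate_task(cfg: TaskConfig, rng: np.random.Generator | None = None) -> Task:
    """Draw component patterns, subvalences and net valences for one task."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_olf, n_vis = _component_pool_sizes(cfg.n_stimuli)
    d = cfg.dim_per_modality
    for _ in range(cfg.max_resample):
        olf = (rng.random((n_olf, d)) < cfg.pattern_density).astype(float)
        vis = (rng.random((n_vis, d)) < cfg.pattern_density).astype(float)
        oi, vi = np.meshgrid(np.arange(n_olf), np.arange(n_vis), indexing="ij")
        oi, vi = oi.ravel(), vi.ravel()
        if cfg.factorizable:
            sv_o = rng.choice([-1.0, 1.0], size=n_olf)
            sv_v = rng.choice([-1.0, 1.0], size=n_vis)
            so, sv = sv_o[oi], sv_v[vi]
            if cfg.combination_rule == "OR":
                valence = np.where((so > 0) | (sv > 0), 1.0, -1.0)
            else:
                valence = np.where((so > 0) & (sv > 0), 1.0, -1.0)
        else:
            valence = rng.choice([-1.0, 1.0], size=len(oi))
            so = sv = np.zeros(len(oi))
        if len(np.unique(valence)) == 2:
            return Task(olf[oi], vis[vi], valence, so, sv, cfg.factorizable)
    raise ValueError("degenerate task: one valence class after bounded resampling")


# ---------------------------------------------------------------------------
# circuit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircuitConfig:
    """KC layer and readout configuration.

    ``architecture="separate"`` splits the KC population half/half, each half
    sampling claws exclusively from one modality's PNs; "shared" lets every
    KC sample from both.  ``reward_mode="separate"`` fits each modality's KC
    synapses only against that modality's subvalence (each reward signal
    modulates only matching synapses) with the two readouts converging
    additively; "shared" is one fit against the net valence.
    """

    n_kc: int = 100
    architecture: str = "shared"
    claws_per_kc: int = 6
    coding_level: float = 0.10
    reward_mode: str = "shared"
    ridge: float = 1e-3
    seed: int | None = None

    def __post_init__(self):
        if self.architecture not in ("shared", "separate"):
            raise ValueError("architecture must be 'shared' or 'separate'")
        if self.reward_mode not in ("shared", "separate"):
            raise ValueError("reward_mode must be 'shared' or 'separate'")
        if not 0 < self.coding_level < 1:
            raise ValueError("coding level must be in (0, 1)")


@dataclass
class KCLayer:
    weights: np.ndarray        # (n_kc, d_olf + d_vis) binary claw weights
    modality_of_kc: np.ndarray  # index into MODALITY_NAMES; -1 = mixed
    d_olf: int
    d_vis: int

    def activity(self, x_olf: np.ndarray, x_vis: np.ndarray,
                 coding_level: float,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        """Binary KC activity with a global threshold hitting the coding level.

        Drives are integer-valued (binary patterns, unit claw weights), so a
        plain quantile threshold cannot realise an arbitrary coding level f;
        ties at the threshold are broken at random (seeded) so that exactly
        round(f · n_kc · n_stimuli) activations occur overall.
        """
        if rng is None:
            rng = np.random.default_rng(0)
        x = np.hstack([x_olf, x_vis])
        drive = x @ self.weights.T
        n = drive.size
        k = int(round(coding_level * n))
        k = min(max(k, 1), n)
        flat = drive.ravel() + rng.random(n) * 1e-6  # tie-break dither << 1
        theta = np.partition(flat, n - k)[n - k]
        return (flat >= theta).astype(float).reshape(drive.shape)


def build_kc_layer(circuit: CircuitConfig, d_olf: int, d_vis: int,
                   rng: np.random.Generator | None = None) -> KCLayer:
    """Sample each KC's claws from its allowed PN pool (unit weights)."""
    if rng is None:
        rng = np.random.default_rng(circuit.seed)
    n_kc, claws = circuit.n_kc, circuit.claws_per_kc
    d_total = d_olf + d_vis
    weights = np.zeros((n_kc, d_total))
    modality = np.full(n_kc, -1, dtype=int)
    if circuit.architecture == "separate":
        half = n_kc // 2
        pools = [(0, np.arange(d_olf)), (1, np.arange(d_olf, d_total))]
        bounds = [(0, half), (half, n_kc)]
        for (mod, pool), (lo, hi) in zip(pools, bounds):
            if claws > len(pool):
                raise ValueError("claw count exceeds the per-modality PN pool")
            for i in range(lo, hi):
                weights[i, rng.choice(pool, size=claws, replace=False)] = 1.0
                modality[i] = mod
    else:
        if claws > d_total:
            raise ValueError("claw count exceeds the PN pool")
        for i in range(n_kc):
            weights[i, rng.choice(d_total, size=claws, replace=False)] = 1.0
    return KCLayer(weights, modality, d_olf, d_vis)


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------

@dataclass
class Readout:
    weights: np.ndarray
    intercept: float


def _ridge_fit(a: np.ndarray, y: np.ndarray, alpha: float) -> Readout:
    model = Ridge(alpha=alpha, fit_intercept=True)
    model.fit(a, y)
    return Readout(model.coef_.copy(), float(model.intercept_))


def _best_threshold(score: np.ndarray, valence: np.ndarray) -> float:
    """Training threshold of a 1-D decision on the summed readout score.

    Candidates are midpoints between consecutive sorted scores plus one
    below the minimum (all-positive); the smallest threshold achieving the
    best training accuracy is chosen, making the rule deterministic.
    """
    s = np.unique(score)
    candidates = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0])
    accs = [np.mean(np.where(score >= t, 1.0, -1.0) == valence) for t in candidates]
    return float(candidates[int(np.argmax(accs))])


def fit_readout(kc_activity: np.ndarray, task: Task, circuit: CircuitConfig,
                layer: KCLayer) -> Readout:
    """Fit the linear MBON readout under the configured reward mode.

    Shared reward: one ridge fit of the ±1 net valence on all KC
    activations.  Separate reward: each modality's KC block is fit only
    against that modality's subvalence, the resulting readouts converge
    additively, and the output threshold of the combined unit is then set on
    the net valence (the per-modality plasticity never sees the net valence;
    only the final spiking threshold does).  The fitted threshold is folded
    into the intercept so downstream evaluation always thresholds at 0.
    Separate reward requires per-modality targets, so it is an error on an
    unfactorizable task (use shared mode there), and modality-pure KC
    blocks, so it requires the separate architecture.
    """
    if np.unique(task.valence).size < 2:
        raise ValueError("need at least one stimulus per valence class")
    if circuit.reward_mode == "shared":
        return _ridge_fit(kc_activity, task.valence, circuit.ridge)
    if not task.factorizable:
        raise ValueError("separate reward signals need per-modality subvalences; "
                         "use reward_mode='shared' for unfactorizable tasks")
    if circuit.architecture != "separate":
        raise ValueError("separate reward signals require the separate architecture")
    weights = np.zeros(kc_activity.shape[1])
    intercept = 0.0
    for mod, target in ((0, task.sub_olf), (1, task.sub_vis)):
        block = layer.modality_of_kc == mod
        fit = _ridge_fit(kc_activity[:, block], target, circuit.ridge)
        weights[block] = fit.weights
        intercept += fit.intercept
    score = kc_activity @ weights + intercept
    threshold = _best_threshold(score, task.valence)
    return Readout(weights, intercept - threshold)


def evaluate(readout: Readout, kc_activity: np.ndarray,
             valence: np.ndarray) -> float:
    """Binary accuracy of the thresholded readout (ties resolved as positive)."""
    score = kc_activity @ readout.weights + readout.intercept
    pred = np.where(score >= 0, 1.0, -1.0)  # tie -> positive
    return float(np.mean(pred == valence))


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    grid: pd.DataFrame           # condition, task, architecture, reward, mean, sem
    samples: dict                # condition -> np.ndarray of accuracies

    def mean(self, condition: str) -> float:
        return float(self.grid.set_index("condition").at[condition, "mean"])

    def sem(self, condition: str) -> float:
        return float(self.grid.set_index("condition").at[condition, "sem"])


def run_condition(task_cfg: TaskConfig, circuit_cfg: CircuitConfig,
                  n_sims: int = 20, seed: int = 0) -> np.ndarray:
    """Accuracy over ``n_sims`` fresh draws of stimuli and wiring."""
    accs = np.empty(n_sims)
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_sims)):
        rng = np.random.default_rng(child)
        task = generate_task(task_cfg, rng)
        layer = build_kc_layer(circuit_cfg, task.x_olf.shape[1],
                               task.x_vis.shape[1], rng)
        activity = layer.activity(task.x_olf, task.x_vis,
                                  circuit_cfg.coding_level, rng)
        readout = fit_readout(activity, task, circuit_cfg, layer)
        accs[i] = evaluate(readout, activity, task.valence)
    return accs


def run_experiment(conditions: dict | None = None, n_sims: int = 20,
                   seed: int = 0) -> ExperimentResult:
    """Run a grid of (task × architecture × reward-mode) conditions.

    ``conditions`` maps a condition name to a ``(TaskConfig, CircuitConfig)``
    pair; the default grid covers the shared-vs-separate KC comparison on
    both tasks plus the reward-signal comparison on the factorizable task.
    Accuracies are summarised as mean ± SEM (sd/√n_sims) over fresh draws.
    """
    if conditions is None:
        fact = TaskConfig(factorizable=True)
        unfact = TaskConfig(factorizable=False)
        conditions = {
            "factorizable/shared_kc": (fact, CircuitConfig(architecture="shared")),
            "factorizable/separate_kc": (fact, CircuitConfig(architecture="separate")),
            "unfactorizable/shared_kc": (unfact, CircuitConfig(architecture="shared")),
            "unfactorizable/separate_kc": (unfact, CircuitConfig(architecture="separate")),
            "factorizable/separate_kc/separate_reward": (
                fact, CircuitConfig(architecture="separate", reward_mode="separate")),
        }
    rows, samples = [], {}
    root = np.random.SeedSequence(seed)
    for (name, (task_cfg, circuit_cfg)), child in zip(conditions.items(),
                                                      root.spawn(len(conditions))):
        accs = run_condition(task_cfg, circuit_cfg, n_sims=n_sims,
                             seed=int(child.generate_state(1)[0] % 2**31))
        samples[name] = accs
        rows.append({
            "condition": name,
            "factorizable": task_cfg.factorizable,
            "architecture": circuit_cfg.architecture,
            "reward_mode": circuit_cfg.reward_mode,
            "mean": float(accs.mean()),
            "sem": float(accs.std(ddof=1) / np.sqrt(n_sims)),
            "n_sims": n_sims,
        })
    return ExperimentResult(pd.DataFrame(rows), samples)
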