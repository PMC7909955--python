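"""Scaled-down synthetic connectomes with plantable wiring structure.

The generator emulates the statistical structure of mushroom-body wiring that
the analyses in this package assume, at a size where every pipeline runs in
seconds:

* ~51 olfactory glomeruli plus a few thermo/hygrosensory and visual input
  channels, each served by 2–4 projection neurons (PNs) whose axons terminate
  in spatially clustered boutons inside a model calyx;
* Kenyon cells (KCs) drawn from the observed subtype proportions, each with a
  claw count around a mean of 5.6; every claw wraps one bouton;
* a *glomerular bias* knob (0 = the exact popularity-proportional random
  sampling null) and a *locality scale* knob (∞ = no spatial structure) that
  plant the two kinds of PN→KC structure the null-model detectors look for;
* modality-segregated KC streams (visual γd / α/βp, thermo-leaning γt, γs and
  α′/β′ap1 types) with planted group labels;
* one MBON per lobe compartment sampling KCs whose axons cross it, MBON
  output targets with a tunable convergence bias, and DANs organised into
  subtypes with block-structured upstream input plus MBON feedback edges.

``generate`` returns the connectome, the calyx geometry (bouton centroids
and claw assignments), and a ground-truth record for parameter-recovery
tests.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (Connectome, LOBE_COMPARTMENTS, write_connectome)
from .spatial import CalyxGeometry

# Subtype census of the 1927 KCs of one hemisphere; default proportions.
KC_TYPE_COUNTS = {
    "KCgm": 590, "KCgd": 99, "KCgt": 8, "KCgs": 4,
    "KCapbp_ap1": 91, "KCapbp_ap2": 127, "KCapbp_m": 119,
    "KCab_p": 60, "KCab_s": 223, "KCab_m": 354, "KCab_c": 252,
}

# Which lobe compartments a KC type's axon crosses.
KC_TYPE_COMPARTMENTS = {
    "KCgm": ("g1", "g2", "g3", "g4", "g5"),
    "KCgd": ("g1", "g2", "g3", "g4", "g5"),
    "KCgt": ("g1", "g2", "g3", "g4", "g5"),
    "KCgs": ("g1", "g2", "g3", "g4", "g5"),
    "KCapbp_ap1": ("ap1", "ap2", "ap3", "bp1", "bp2"),
    "KCapbp_ap2": ("ap1", "ap2", "ap3", "bp1", "bp2"),
    "KCapbp_m": ("ap1", "ap2", "ap3", "bp1", "bp2"),
    "KCab_p": ("a1", "a2", "a3", "b1", "b2"),
    "KCab_s": ("a1", "a2", "a3", "b1", "b2"),
    "KCab_m": ("a1", "a2", "a3", "b1", "b2"),
    "KCab_c": ("a1", "a2", "a3", "b1", "b2"),
}

# Per-type sensory source mixture: the fraction of a KC's claws drawn from
# channels of each modality.  Visual types (γd, α/βp) take >90% visual input;
# γt, γs and α′/β′ap1 lean on thermo/hygrosensory channels; the rest are
# purely olfactory.
DEFAULT_MODALITY_MIX = {
    "KCgd": {"visual": 0.9, "olfactory": 0.1},
    "KCab_p": {"visual": 0.9, "olfactory": 0.1},
    "KCgt": {"thermo_hygro": 0.7, "olfactory": 0.3},
    "KCgs": {"thermo_hygro": 0.6, "olfactory": 0.4},
    "KCapbp_ap1": {"thermo_hygro": 0.4, "olfactory": 0.6},
}

#: group label implied by a type's modality mix at the default 0.25 threshold
def _planted_group(mix: dict) -> str:
    th = mix.get("thermo_hygro", 0.0)
    vi = mix.get("visual", 0.0)
    if max(th, vi) >= 0.25:
        return "olfactory_thermo_hygro" if th >= vi else "olfactory_visual"
    return "olfactory"


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic connectome; defaults are the study conditions.

    ``glomerular_bias = 0`` and ``locality_scale = inf`` give the exact
    random-sampling null in which claws pick boutons uniformly, i.e. each
    uPN is sampled in proportion to the boutons (and hence KC connections)
    it provides.  Positive bias tilts each KC type's glomerulus preferences
    by i.i.d. log-normal factors of scale ``glomerular_bias``; a finite
    locality scale makes claws prefer boutons near their anchor with an
    exponential distance kernel.
    """

    n_glomeruli: int = 51
    n_thermo_channels: int = 4
    n_visual_channels: int = 6
    pns_per_glomerulus: tuple = (2, 4)          # inclusive uniform range
    n_kc: int = 200
    kc_type_proportions: dict | None = None      # default ∝ KC_TYPE_COUNTS
    claw_mean: float = 5.6
    claw_dispersion: float = 1.0                 # 0 = deterministic round(mean)
    boutons_per_pn_mean: float = 6.0
    boutons_per_pn_sd: float = 2.0
    calyx_radius: float = 25.0                   # µm, model calyx sphere
    glomerulus_jitter: float = 5.0               # µm, bouton spread per glomerulus
    glomerular_bias: float = 0.0
    locality_scale: float = math.inf             # µm
    modality_mix: dict | None = None             # default DEFAULT_MODALITY_MIX
    synapses_per_claw_min: int = 5
    synapses_per_claw_mean: float = 8.0
    n_mbon: int = 15
    kc_mbon_p: float = 0.3
    n_dan: int = 12
    n_dan_subtypes: int = 3
    n_dan_inputs: int = 30
    dan_input_noise_p: float = 0.1
    n_mbon_targets: int = 40
    mbon_targets_per_cell: int = 10
    mbon_target_hub_frac: float = 0.25
    mbon_target_hub_weight: float = 4.0
    mbon_dan_self_p: float = 0.6
    mbon_dan_cross_p: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.kc_type_proportions is None:
            total = sum(KC_TYPE_COUNTS.values())
            self.kc_type_proportions = {k: v / total for k, v in KC_TYPE_COUNTS.items()}
        s = sum(self.kc_type_proportions.values())
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError("kc_type_proportions must sum to 1")
        if self.modality_mix is None:
            self.modality_mix = {k: dict(v) for k, v in DEFAULT_MODALITY_MIX.items()}
        for val in (self.n_glomeruli, self.n_kc, self.n_mbon, self.n_dan):
            if val <= 0:
                raise ValueError("counts must be positive")
        if self.claw_mean <= 0:
            raise ValueError("claw mean must be positive")


@dataclass
class GroundTruth:
    """Planted structure, for parameter-recovery tests."""

    kc_groups: dict            # kc_id -> modality group label
    kc_types: dict             # kc_id -> cell type
    glomerulus_probs: dict     # kc_type -> {channel: relative weight}
    dan_subtypes: dict         # dan_id -> subtype label
    claw_assignment: pd.DataFrame  # kc_id, bouton_id

    def to_json(self, path) -> None:
        payload = {
            "kc_groups": self.kc_groups,
            "kc_types": self.kc_types,
            "glomerulus_probs": self.glomerulus_probs,
            "dan_subtypes": self.dan_subtypes,
            "claw_assignment": self.claw_assignment.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def generate_claw_counts(config: GeneratorConfig, rng: np.random.Generator,
                         n: int | None = None) -> np.ndarray:
    """Per-KC dendritic claw counts (integer, ≥ 1).

    With positive dispersion the family is a shifted Poisson,
    1 + Poisson(mean − 1), matching the configured mean; zero dispersion
    gives the deterministic round(mean).
    """
    n = config.n_kc if n is None else n
    if config.claw_dispersion == 0:
        return np.full(n, max(1, round(config.claw_mean)), dtype=int)
    return 1 + rng.poisson(config.claw_mean - 1.0, size=n)


def _uniform_ball(rng, n, radius):
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1 / 3)
    return v * r[:, None]


def _sample_bouton(rng, anchor, xyz, base_w, scale):
    """One bouton index; p ∝ base_w · exp(−d/scale), stable in log space."""
    if scale == 0:
        d = np.linalg.norm(xyz - anchor, axis=1)
        d[base_w <= 0] = np.inf
        return int(np.argmin(d))
    logw = np.where(base_w > 0, np.log(np.where(base_w > 0, base_w, 1.0)), -np.inf)
    if np.isfinite(scale):
        logw = logw - np.linalg.norm(xyz - anchor, axis=1) / scale
    logw = logw - logw.max()
    p = np.exp(logw)
    return int(rng.choice(len(xyz), p=p / p.sum()))


def plant_spatial_locality(geometry: CalyxGeometry, locality_scale: float,
                           rng: np.random.Generator) -> CalyxGeometry:
    """Reassign every claw to a bouton with a distance-decaying kernel.

    Selection probability decays as exp(−d/scale) from the claw's anchor;
    scale → 0 takes the nearest bouton, scale = ∞ is uniform over boutons.
    """
    xyz = geometry.bouton_xyz()
    ids = np.asarray(geometry.boutons.index)
    base = np.ones(len(ids))
    claws = geometry.claws.copy()
    anchors = claws[["anchor_x", "anchor_y", "anchor_z"]].to_numpy(dtype=float)
    claws["bouton_id"] = [
        ids[_sample_bouton(rng, a, xyz, base, locality_scale)] for a in anchors
    ]
    return CalyxGeometry(geometry.boutons.copy(), claws)


@dataclass
class GenerateResult:
    connectome: Connectome
    geometry: CalyxGeometry
    ground_truth: GroundTruth


def generate(config: GeneratorConfig) -> GenerateResult:
    """Draw one synthetic connectome; byte-identical given the config seed."""
    rng = np.random.default_rng(config.seed)

    # --- sensory channels and PNs ----------------------------------------
    channels = (
        [("G%02d" % i, "olfactory") for i in range(config.n_glomeruli)]
        + [("T%02d" % i, "thermo_hygro") for i in range(config.n_thermo_channels)]
        + [("V%02d" % i, "visual") for i in range(config.n_visual_channels)]
    )
    lo, hi = config.pns_per_glomerulus
    pn_rows, pn_of_channel = [], {}
    for glom, modality in channels:
        k = int(rng.integers(lo, hi + 1))
        pn_of_channel[glom] = []
        for j in range(k):
            pid = f"PN_{glom}_{j}"
            pn_rows.append({"neuron_id": pid, "super_class": "PN",
                            "cell_type": f"uPN_{glom}", "subtype": None,
                            "modality": modality, "glomerulus": glom,
                            "compartments_dendrite": frozenset(),
                            "compartments_axon": frozenset({"CA"})})
            pn_of_channel[glom].append(pid)

    # --- boutons in the model calyx ---------------------------------------
    centers = {glom: c for (glom, _), c in
               zip(channels, _uniform_ball(rng, len(channels), config.calyx_radius))}
    bouton_rows = []
    for glom, modality in channels:
        for pid in pn_of_channel[glom]:
            nb = max(1, int(round(rng.normal(config.boutons_per_pn_mean,
                                             config.boutons_per_pn_sd))))
            pos = centers[glom] + rng.normal(0.0, config.glomerulus_jitter, (nb, 3))
            for p in pos:
                bouton_rows.append({"bouton_id": f"B{len(bouton_rows):05d}",
                                    "pn_id": pid, "glomerulus": glom,
                                    "modality": modality,
                                    "x": p[0], "y": p[1], "z": p[2]})
    boutons = pd.DataFrame(bouton_rows).set_index("bouton_id")
    bouton_xyz = boutons[["x", "y", "z"]].to_numpy(dtype=float)
    bouton_modality = boutons["modality"].to_numpy()
    bouton_glom = boutons["glomerulus"].to_numpy()
    bouton_ids = np.asarray(boutons.index)

    # --- KC population -----------------------------------------------------
    types = list(config.kc_type_proportions)
    type_counts = rng.multinomial(config.n_kc,
                                  [config.kc_type_proportions[t] for t in types])
    kc_types = np.repeat(types, type_counts)
    kc_ids = [f"KC{i:04d}" for i in range(config.n_kc)]
    claw_counts = generate_claw_counts(config, rng)
    total_claws = int(claw_counts.sum())
    if total_claws > 10 * len(boutons):
        raise ValueError("infeasible config: far more claws than bouton capacity")

    # per-(type, channel) planted preference factors
    channel_names = [g for g, _ in channels]
    glom_factors = {}
    for t in types:
        if config.glomerular_bias == 0:
            glom_factors[t] = np.ones(len(channel_names))
        else:
            glom_factors[t] = np.exp(
                config.glomerular_bias * rng.standard_normal(len(channel_names)))
    channel_index = {g: i for i, g in enumerate(channel_names)}
    bouton_channel_idx = np.array([channel_index[g] for g in bouton_glom])

    kc_centers = _uniform_ball(rng, config.n_kc, config.calyx_radius)
    mix_of = {t: config.modality_mix.get(t, {"olfactory": 1.0}) for t in types}

    claw_rows, edge_acc, synapse_rows = [], {}, []
    for i, kc in enumerate(kc_ids):
        t = kc_types[i]
        mix_mods = list(mix_of[t])
        mix_p = np.array([mix_of[t][m] for m in mix_mods])
        mix_p = mix_p / mix_p.sum()
        factors = glom_factors[t][bouton_channel_idx]
        for _ in range(claw_counts[i]):
            modality = mix_mods[int(rng.choice(len(mix_mods), p=mix_p))]
            mask = bouton_modality == modality
            base = np.where(mask, factors, 0.0)
            j = _sample_bouton(rng, kc_centers[i], bouton_xyz, base,
                               config.locality_scale)
            n_syn = config.synapses_per_claw_min + rng.poisson(
                max(config.synapses_per_claw_mean - config.synapses_per_claw_min, 0.0))
            pn = boutons["pn_id"].iloc[j]
            claw_rows.append({"kc_id": kc, "bouton_id": bouton_ids[j],
                              "anchor_x": kc_centers[i, 0],
                              "anchor_y": kc_centers[i, 1],
                              "anchor_z": kc_centers[i, 2],
                              "n_synapses": int(n_syn), "modality": modality})
            edge_acc[(pn, kc)] = edge_acc.get((pn, kc), 0) + int(n_syn)
            sites = bouton_xyz[j] + rng.normal(0.0, 0.5, (int(n_syn), 3))
            for p in sites:
                synapse_rows.append({"pre_id": pn, "post_id": kc,
                                     "x_um": p[0], "y_um": p[1], "z_um": p[2],
                                     "region": "CA"})
    claws = pd.DataFrame(claw_rows)
    geometry = CalyxGeometry(boutons[["pn_id", "glomerulus", "modality",
                                      "x", "y", "z"]].copy(), claws)

    kc_rows = []
    for i, kc in enumerate(kc_ids):
        t = kc_types[i]
        kc_rows.append({"neuron_id": kc, "super_class": "KC", "cell_type": t,
                        "subtype": None, "modality": None, "glomerulus": None,
                        "compartments_dendrite": frozenset({"CA"}),
                        "compartments_axon": frozenset(KC_TYPE_COMPARTMENTS[t])})

    # --- MBONs: one per compartment, sampling KCs that cross it ------------
    compartments = LOBE_COMPARTMENTS[:config.n_mbon]
    mbon_rows, mbon_ids = [], []
    for m, comp in enumerate(compartments):
        mid = f"MBON{m + 1:02d}"
        mbon_ids.append(mid)
        mbon_rows.append({"neuron_id": mid, "super_class": "MBON",
                          "cell_type": mid, "subtype": None, "modality": None,
                          "glomerulus": None,
                          "compartments_dendrite": frozenset({comp}),
                          "compartments_axon": frozenset()})
        for i, kc in enumerate(kc_ids):
            if comp in KC_TYPE_COMPARTMENTS[kc_types[i]] and rng.random() < config.kc_mbon_p:
                edge_acc[(kc, mid)] = 5 + int(rng.poisson(5))

    # --- MBON downstream targets with a convergence (hub) bias -------------
    target_ids = [f"TN{i:03d}" for i in range(config.n_mbon_targets)]
    n_hub = max(1, int(round(config.mbon_target_hub_frac * len(target_ids))))
    target_w = np.ones(len(target_ids))
    target_w[:n_hub] = config.mbon_target_hub_weight
    target_p = target_w / target_w.sum()
    target_rows = [{"neuron_id": t, "super_class": "other", "cell_type": "central",
                    "subtype": None, "modality": None, "glomerulus": None,
                    "compartments_dendrite": frozenset(),
                    "compartments_axon": frozenset()} for t in target_ids]
    for mid in mbon_ids:
        picks = rng.choice(len(target_ids),
                           size=min(config.mbon_targets_per_cell, len(target_ids)),
                           replace=False, p=target_p)
        for j in picks:
            edge_acc[(mid, target_ids[j])] = 12 + int(rng.poisson(6))

    # --- DANs: subtype blocks of shared upstream input ----------------------
    input_ids = [f"IN{i:03d}" for i in range(config.n_dan_inputs)]
    input_rows = [{"neuron_id": t, "super_class": "other", "cell_type": "dan_input",
                   "subtype": None, "modality": None, "glomerulus": None,
                   "compartments_dendrite": frozenset(),
                   "compartments_axon": frozenset()} for t in input_ids]
    # give candidates some input synapses so convergence nulls have weights
    for t in target_ids + input_ids:
        src = input_ids[int(rng.integers(len(input_ids)))]
        if src != t:
            edge_acc[(src, t)] = edge_acc.get((src, t), 0) + 1 + int(rng.poisson(3))

    dan_rows, dan_subtypes = [], {}
    block = max(1, config.n_dan_inputs // config.n_dan_subtypes)
    for d in range(config.n_dan):
        did = f"DAN{d + 1:02d}"
        sub = d % config.n_dan_subtypes
        dan_subtypes[did] = f"sub{sub}"
        comp = compartments[sub % len(compartments)]
        dan_rows.append({"neuron_id": did, "super_class": "DAN",
                         "cell_type": f"PAM{sub + 1:02d}", "subtype": f"sub{sub}",
                         "modality": None, "glomerulus": None,
                         "compartments_dendrite": frozenset(),
                         "compartments_axon": frozenset({comp})})
        for src in input_ids[sub * block:(sub + 1) * block]:
            edge_acc[(src, did)] = 10 + int(rng.poisson(5))
        for src in input_ids:
            if src not in input_ids[sub * block:(sub + 1) * block] \
                    and rng.random() < config.dan_input_noise_p:
                edge_acc[(src, did)] = 1 + int(rng.poisson(1))
        # MBON feedback: same-compartment and/or cross-compartment
        same_mbon = mbon_ids[compartments.index(comp)]
        if rng.random() < config.mbon_dan_self_p:
            edge_acc[(same_mbon, did)] = 8 + int(rng.poisson(4))
        if rng.random() < config.mbon_dan_cross_p:
            others = [m for m in mbon_ids if m != same_mbon]
            edge_acc[(others[int(rng.integers(len(others)))], did)] = 8 + int(rng.poisson(4))

    neurons = pd.DataFrame(pn_rows + kc_rows + mbon_rows + target_rows
                           + input_rows + dan_rows).set_index("neuron_id")
    edges = pd.DataFrame(
        [{"pre_id": k[0], "post_id": k[1], "weight": w, "post_site_class": "dendrite"}
         for k, w in edge_acc.items()])
    synapses = pd.DataFrame(synapse_rows)
    connectome = Connectome(neurons, edges, synapses)

    truth = GroundTruth(
        kc_groups={kc: _planted_group(mix_of[kc_types[i]])
                   for i, kc in enumerate(kc_ids)},
        kc_types={kc: kc_types[i] for i, kc in enumerate(kc_ids)},
        glomerulus_probs={t: dict(zip(channel_names, glom_factors[t].tolist()))
                          for t in types},
        dan_subtypes=dan_subtypes,
        claw_assignment=claws[["kc_id", "bouton_id"]].copy(),
    )
    return GenerateResult(connectome, geometry, truth)


def write_outputs(result: GenerateResult, outdir) -> dict:
    """Write the CSV dialects plus ground-truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "neurons": outdir / "neurons.csv",
        "edges": outdir / "edges.csv",
        "synapses": outdir / "synapses.csv",
        "boutons": outdir / "boutons.csv",
        "claws": outdir / "claws.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_connectome(result.connectome, paths["neurons"], paths["edges"],
                     paths["synapses"])
    result.geometry.boutons.to_csv(paths["boutons"], index_label="bouton_id")
    result.geometry.claws.to_csv(paths["claws"], index=False)
    result.ground_truth.to_json(paths["ground_truth"])
    return paths
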