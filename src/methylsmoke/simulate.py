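"""Synthetic methylation-cohort generator.

Emulates a two-ethnicity, 450k-style methylation study of smoking: a
stratified sample sheet (ethnicity x smoking status with ages, doses and
chip assignments), a probes x samples beta matrix with injected
smoking/ethnicity/interaction effects, cell-mixture confounding, per-chip
batch offsets and logit-normal noise, per-cell detection p-values, and a
reference panel of smoking-associated CpGs for the weighted smoking
score. Ground truth for every injected effect is returned alongside so
recovery can be tested downstream.

Effects are specified on the beta (methylation-fraction) scale and
injected by shifting the probe's mean beta before the logit2 transform;
because the residual noise is symmetric on the logit scale and the
inverse logit is monotone, the group *median* beta equals the shifted
mean beta exactly, so injected beta-scale effects are recovered by median
differences without approximation error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import beta_to_m, m_to_beta
from .score import HYPER, HYPO, compute_weights

__all__ = [
    "ETHNICITIES", "SMOKING_STATUSES", "DEFAULT_STRATA",
    "CohortConfig", "GroundTruth",
    "generate_manifest", "simulate_sheet", "simulate_cohort",
    "simulate_cell_structure", "generate_reference_panel",
    "config_with_panel", "write_cohort",
]

ETHNICITIES = ("European", "SouthAsian")
SMOKING_STATUSES = ("never", "former", "current")

#: default stratum sizes (ethnicity, smoking status) -> n, mirroring a
#: bi-ethnic cohort of 189 men with never/former/current smokers.
DEFAULT_STRATA: Mapping[tuple, int] = {
    ("European", "never"): 65, ("SouthAsian", "never"): 64,
    ("European", "former"): 14, ("SouthAsian", "former"): 10,
    ("European", "current"): 16, ("SouthAsian", "current"): 20,
}

# per-stratum (mean, sd) phenotype parameters for the generator
_AGE = {
    ("European", "never"): (48.5, 4.6), ("SouthAsian", "never"): (48.3, 4.3),
    ("European", "former"): (47.9, 4.2), ("SouthAsian", "former"): (46.6, 4.4),
    ("European", "current"): (46.9, 3.9), ("SouthAsian", "current"): (47.8, 4.3),
}
_CPD = {
    ("European", "former"): (23.0, 12.0), ("SouthAsian", "former"): (13.0, 9.0),
    ("European", "current"): (23.0, 9.0), ("SouthAsian", "current"): (13.0, 6.0),
}
_AGE_STARTED = {
    ("European", "former"): (17.9, 3.6), ("SouthAsian", "former"): (21.5, 6.5),
    ("European", "current"): (17.9, 4.8), ("SouthAsian", "current"): (22.3, 5.8),
}
_QUIT = {
    ("European", "former"): (12.9, 7.9), ("SouthAsian", "former"): (12.1, 8.0),
}

_ISLAND_RELATIONS = ("CpG Island", "North Shore", "South Shore",
                     "North Shelf", "South Shelf", "Open Sea")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one simulated cohort.

    Smoking effects are beta-scale differences (current - never), signed;
    former smokers receive ``former_attenuation`` times the effect.
    ``ethnic_main_cpgs`` maps signal-CpG index -> beta offset added to all
    South Asian samples (visible in never smokers as a main effect).
    ``interaction_cpg`` is (signal index, effect_european, effect_south_asian)
    giving that CpG an ethnicity-specific smoking effect.
    ``ethnic_dose_factor`` rescales each ethnicity's smoking effects (a
    lighter-smoking group gets a factor < 1), and ``dose_scaled=True``
    additionally multiplies each smoker's effect by cigarettes/day / 20.
    """

    n_per_stratum: Mapping[tuple, int] = field(
        default_factory=lambda: dict(DEFAULT_STRATA))
    n_probes: int = 1000
    n_signal_cpgs: int = 10
    effect_sizes: Optional[Sequence[float]] = None
    signal_baselines: Optional[Sequence[float]] = None
    ethnic_main_cpgs: Mapping[int, float] = field(default_factory=dict)
    interaction_cpg: Optional[tuple] = None
    former_attenuation: float = 0.0
    n_chips: int = 8
    batch_sd: float = 0.05
    noise_sd: float = 0.25
    n_cell_types: int = 3
    n_cell_probes: int = 50
    cell_shift: float = 0.0
    cell_concentration: float = 200.0
    detection_fail_fraction: float = 0.0
    sample_fail_fractions: Mapping[int, float] = field(default_factory=dict)
    dose_scaled: bool = False
    ethnic_dose_factor: Mapping[str, float] = field(
        default_factory=lambda: {"European": 1.0, "SouthAsian": 1.0})
    homology_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> "CohortConfig":
        for key, n in self.n_per_stratum.items():
            if key[0] not in ETHNICITIES or key[1] not in SMOKING_STATUSES:
                raise ValueError(f"unknown stratum {key}")
            if n <= 0:
                raise ValueError(f"stratum {key} has non-positive count {n}")
        if self.n_probes < 200:
            raise ValueError("n_probes must be >= 200")
        if self.n_signal_cpgs < 0:
            raise ValueError("n_signal_cpgs must be >= 0")
        reserved = self.n_signal_cpgs + (self.n_cell_probes if self.n_cell_types else 0)
        if reserved > self.n_probes:
            raise ValueError("signal + cell probes exceed n_probes")
        if self.effect_sizes is not None:
            eff = np.asarray(self.effect_sizes, dtype=float)
            if len(eff) != self.n_signal_cpgs:
                raise ValueError("effect_sizes length must equal n_signal_cpgs")
            if np.any(np.abs(eff) >= 1):
                raise ValueError("effect sizes must lie in (-1, 1)")
        if not 0.0 <= self.former_attenuation <= 1.0:
            raise ValueError("former_attenuation must lie in [0, 1]")
        if self.n_chips < 1:
            raise ValueError("n_chips must be >= 1")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ValueError("noise_sd and batch_sd must be non-negative")
        for idx in self.ethnic_main_cpgs:
            if not 0 <= idx < self.n_signal_cpgs:
                raise ValueError(f"ethnic_main_cpgs index {idx} out of range")
        if self.interaction_cpg is not None:
            idx = self.interaction_cpg[0]
            if not 0 <= idx < self.n_signal_cpgs:
                raise ValueError("interaction_cpg index out of range")
        return self

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_stratum.values())


@dataclass
class GroundTruth:
    """Everything injected into a simulated cohort, keyed by id."""

    smoking_effects: pd.Series            # beta scale, per signal probe
    ethnic_effects: pd.Series             # South Asian offset, per probe
    interaction: Optional[dict]           # probe_id, effect_european, effect_south_asian
    baseline_betas: pd.Series             # per probe
    cell_proportions: Optional[pd.DataFrame]   # samples x cell types
    cell_profiles: Optional[pd.DataFrame]      # cell probes x cell types
    batch_offsets: pd.Series              # per chip, logit scale
    signal_probes: list
    cell_probes: list

    def to_json(self, path) -> None:
        payload = {
            "smoking_effects": self.smoking_effects.to_dict(),
            "ethnic_effects": self.ethnic_effects.to_dict(),
            "interaction": self.interaction,
            "baseline_betas": self.baseline_betas.to_dict(),
            "cell_proportions": (None if self.cell_proportions is None
                                 else self.cell_proportions.to_dict()),
            "cell_profiles": (None if self.cell_profiles is None
                              else self.cell_profiles.to_dict()),
            "batch_offsets": self.batch_offsets.to_dict(),
            "signal_probes": self.signal_probes,
            "cell_probes": self.cell_probes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _probe_ids(n: int) -> list:
    return [f"cg{i:08d}" for i in range(n)]


def generate_manifest(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Array manifest: probe id, 1-based coordinates, locus label, island
    relation and multi-homology flag.

    Probes are laid out in consecutive 3-probe loci so that sentinel
    selection has multi-CpG loci to work with. Signal and cell probes are
    never homology-flagged (panel CpGs passed QC by construction).
    """
    n = config.n_probes
    ids = _probe_ids(n)
    idx = np.arange(n)
    manifest = pd.DataFrame({
        "probe_id": ids,
        "chr": (idx % 22 + 1),
        "position": 15000 + 937 * idx,  # 1-based
        "locus": [f"LOC{i // 3:05d}" for i in idx],
        "island_relation": [_ISLAND_RELATIONS[i % len(_ISLAND_RELATIONS)] for i in idx],
    })
    flags = rng.random(n) < config.homology_fraction
    flags[: config.n_signal_cpgs] = False
    if config.n_cell_types and config.n_cell_probes:
        flags[n - config.n_cell_probes:] = False
    manifest["homology"] = flags
    return manifest


def _truncated_normal(rng, mean, sd, size, low, high):
    out = rng.normal(mean, sd, size)
    return np.clip(out, low, high)


def simulate_sheet(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Stratified sample sheet with phenotype, dose and chip columns.

    Never smokers have missing dose fields; years since quitting is only
    defined for former smokers.
    """
    rows = []
    for (eth, status), n in config.n_per_stratum.items():
        age = _truncated_normal(rng, *_AGE[(eth, status)], n, 40.0, 55.0)
        if status == "never":
            cpd = np.full(n, np.nan)
            started = np.full(n, np.nan)
            quit_ = np.full(n, np.nan)
        else:
            cpd = np.round(_truncated_normal(rng, *_CPD[(eth, status)], n, 1.0, 60.0))
            started = _truncated_normal(rng, *_AGE_STARTED[(eth, status)], n, 10.0, 35.0)
            if status == "former":
                quit_ = _truncated_normal(rng, *_QUIT[(eth, status)], n, 0.5, 30.0)
                quit_ = np.minimum(quit_, age - started - 1.0)
            else:
                quit_ = np.full(n, np.nan)
        for i in range(n):
            rows.append((eth, status, age[i], cpd[i], started[i], quit_[i]))
    sheet = pd.DataFrame(rows, columns=[
        "ethnicity", "smoking_status", "age_years", "cigarettes_per_day",
        "age_started_years", "years_since_quitting"])
    sheet.insert(0, "sample_id", [f"S{i:04d}" for i in range(len(sheet))])
    chips = rng.permutation(np.arange(len(sheet)) % config.n_chips)
    sheet["chip_id"] = [f"chip{c:02d}" for c in chips]
    return sheet


def simulate_cell_structure(config: CohortConfig, sheet: pd.DataFrame,
                            rng: Optional[np.random.Generator] = None):
    """Cell-type reference profiles and per-sample mixture proportions.

    Proportions are Dirichlet draws whose mean shifts by ``cell_shift``
    toward the first cell type in current smokers (emulating the
    granulocyte shift of active smoking). Profiles give each cell type's
    beta at the discriminating probes.

    Returns (cell_profiles, proportions).
    """
    if config.n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    k = config.n_cell_types
    types = [f"cell{j}" for j in range(k)]
    cell_probes = _probe_ids(config.n_probes)[config.n_probes - config.n_cell_probes:]
    profiles = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(config.n_cell_probes, k)),
        index=cell_probes, columns=types)

    base_mean = np.arange(k, 0, -1, dtype=float)
    base_mean /= base_mean.sum()
    props = np.empty((len(sheet), k))
    current = (sheet["smoking_status"] == "current").values
    for is_current, mask in ((False, ~current), (True, current)):
        if not mask.any():
            continue
        mean = base_mean.copy()
        if is_current and config.cell_shift:
            mean[0] += config.cell_shift
            mean[1:] *= (1.0 - mean[0]) / mean[1:].sum()
        if np.any(mean <= 0):
            raise ValueError("cell_shift pushes a mean proportion to <= 0")
        props[mask] = rng.dirichlet(config.cell_concentration * mean, mask.sum())
    if not np.allclose(props.sum(axis=1), 1.0, atol=1e-9):
        raise RuntimeError("cell proportions do not sum to one")  # unreachable
    proportions = pd.DataFrame(props, index=sheet["sample_id"].values, columns=types)
    return profiles, proportions


def _draw_baselines(rng, effects):
    """Valid never-smoker baseline betas for given signed effects."""
    lows = np.where(effects < 0, -effects + 0.05, 0.05)
    highs = np.where(effects > 0, 0.95 - effects, 0.95)
    if np.any(lows >= highs):
        raise ValueError("effect sizes leave no room for a valid baseline")
    return rng.uniform(lows, highs)


def simulate_cohort(config: CohortConfig):
    """Generate one cohort.

    Returns ``(beta, sheet, detection_p, truth)`` where ``beta`` and
    ``detection_p`` are probes x samples DataFrames, ``sheet`` the sample
    sheet and ``truth`` a :class:`GroundTruth`. Identical configs (same
    seed) give bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    manifest = generate_manifest(config, rng)
    sheet = simulate_sheet(config, rng)
    n_probes, n_samples = config.n_probes, len(sheet)
    probe_ids = manifest["probe_id"].values

    # signed beta-scale effects and never-smoker baselines at signal CpGs
    if config.n_signal_cpgs:
        if config.effect_sizes is None:
            mags = rng.uniform(0.05, 0.25, config.n_signal_cpgs)
            signs = np.where(rng.random(config.n_signal_cpgs) < 0.7, -1.0, 1.0)
            effects = mags * signs
        else:
            effects = np.asarray(config.effect_sizes, dtype=float)
        if config.signal_baselines is None:
            sig_base = _draw_baselines(rng, effects)
        else:
            sig_base = np.asarray(config.signal_baselines, dtype=float)
    else:
        effects = np.empty(0)
        sig_base = np.empty(0)

    # baseline betas: bimodal mixture typical of array methylation
    component = rng.random(n_probes)
    baseline = np.where(component < 0.4, rng.beta(2.0, 8.0, n_probes),
                        np.where(component < 0.8, rng.beta(8.0, 2.0, n_probes),
                                 rng.uniform(0.2, 0.8, n_probes)))
    baseline = np.clip(baseline, 0.01, 0.99)
    baseline[: config.n_signal_cpgs] = sig_base

    # per-sample effect multiplier for smoking status and dose
    status = sheet["smoking_status"].values
    eth = sheet["ethnicity"].values
    mult = np.where(status == "current", 1.0,
                    np.where(status == "former", config.former_attenuation, 0.0))
    mult = mult * np.array([config.ethnic_dose_factor.get(e, 1.0) for e in eth])
    if config.dose_scaled:
        cpd = sheet["cigarettes_per_day"].values
        dose = np.where(np.isfinite(cpd), cpd / 20.0, 0.0)
        mult = mult * dose

    # mean beta per (probe, sample)
    mean_beta = np.repeat(baseline[:, None], n_samples, axis=1)
    if config.n_signal_cpgs:
        delta = effects[:, None] * mult[None, :]
        if config.interaction_cpg is not None:
            i, eff_eu, eff_sa = config.interaction_cpg
            eff_by_eth = np.where(eth == "European", eff_eu, eff_sa)
            status_mult = np.where(status == "current", 1.0,
                                   np.where(status == "former",
                                            config.former_attenuation, 0.0))
            delta[i] = eff_by_eth * status_mult
        mean_beta[: config.n_signal_cpgs] += delta
        for idx, offset in config.ethnic_main_cpgs.items():
            mean_beta[idx] += np.where(eth == "SouthAsian", offset, 0.0)

    truth_props = truth_profiles = None
    cell_probe_ids: list = []
    if config.n_cell_types and config.n_cell_probes:
        truth_profiles, truth_props = simulate_cell_structure(
            config, sheet, rng=rng)
        cell_probe_ids = list(truth_profiles.index)
        mixture = truth_props.values @ truth_profiles.values.T  # samples x probes
        mean_beta[n_probes - config.n_cell_probes:] = mixture.T

    if np.any((mean_beta <= 0.001) | (mean_beta >= 0.999)):
        raise ValueError("combined effects push a mean beta outside (0.001, 0.999)")

    # logit, batch, noise, inverse logit
    m = np.asarray(beta_to_m(mean_beta))
    batch_offsets = pd.Series(rng.normal(0.0, config.batch_sd, config.n_chips),
                              index=[f"chip{c:02d}" for c in range(config.n_chips)])
    m += batch_offsets[sheet["chip_id"].values].values[None, :]
    if config.noise_sd:
        m += rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    beta = np.asarray(m_to_beta(m))

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sheet["sample_id"].values)

    # detection p-values: near 0 for good cells, >= 0.01 for failures
    detp = rng.uniform(0.0, 1e-4, size=(n_probes, n_samples))
    if config.detection_fail_fraction:
        fail = rng.random((n_probes, n_samples)) < config.detection_fail_fraction
        detp[fail] = rng.uniform(0.01, 1.0, int(fail.sum()))
    for sample_idx, frac in config.sample_fail_fractions.items():
        fail = rng.random(n_probes) < frac
        detp[fail, sample_idx] = rng.uniform(0.01, 1.0, int(fail.sum()))
    detp_df = pd.DataFrame(detp, index=probe_ids, columns=sheet["sample_id"].values)

    signal_probes = list(probe_ids[: config.n_signal_cpgs])
    ethnic_effects = pd.Series(
        {probe_ids[i]: off for i, off in config.ethnic_main_cpgs.items()},
        dtype=float)
    interaction = None
    if config.interaction_cpg is not None:
        i, eff_eu, eff_sa = config.interaction_cpg
        interaction = {"probe_id": probe_ids[i],
                       "effect_european": float(eff_eu),
                       "effect_south_asian": float(eff_sa)}
    truth = GroundTruth(
        smoking_effects=pd.Series(effects, index=signal_probes, dtype=float),
        ethnic_effects=ethnic_effects,
        interaction=interaction,
        baseline_betas=pd.Series(baseline, index=probe_ids),
        cell_proportions=truth_props,
        cell_profiles=truth_profiles,
        batch_offsets=batch_offsets,
        signal_probes=signal_probes,
        cell_probes=cell_probe_ids,
    )
    beta_df.attrs["manifest"] = manifest
    return beta_df, sheet, detp_df, truth


def generate_reference_panel(config: CohortConfig, seed: int,
                             panel_size: int = 183) -> pd.DataFrame:
    """Reference panel of smoking-associated CpGs for the smoking score.

    Emulates a published catalogue: per CpG a direction (hyper- or
    hypomethylated in smokers, 70% hypo), an effect-size magnitude in the
    2-15% beta range, the never-smoker reference median beta, and the
    weight |effect| / mean|effect|. Panel CpGs are the first
    ``panel_size`` manifest probes (the simulator's signal block), so a
    cohort simulated with :func:`config_with_panel` realises exactly the
    panel's effects.
    """
    if panel_size < 2:
        raise ValueError("panel must contain at least 2 CpGs")
    usable = config.n_probes - (config.n_cell_probes if config.n_cell_types else 0)
    if panel_size > usable:
        raise ValueError(f"panel size {panel_size} exceeds the {usable} "
                         "manifest probes available outside the cell block")
    rng = np.random.default_rng(seed)
    magnitudes = rng.uniform(0.02, 0.15, panel_size)
    hypo = rng.random(panel_size) < 0.7
    direction = np.where(hypo, HYPO, HYPER)
    signed = np.where(hypo, -magnitudes, magnitudes)
    reference_beta = _draw_baselines(rng, signed)
    panel = pd.DataFrame({
        "probe_id": _probe_ids(config.n_probes)[:panel_size],
        "direction": direction,
        "effect_size": magnitudes,
        "reference_beta": reference_beta,
        "weight": compute_weights(magnitudes),
    })
    return panel


def config_with_panel(config: CohortConfig, panel: pd.DataFrame) -> CohortConfig:
    """A config whose signal CpGs realise the panel's effects exactly.

    Signal CpG i gets the panel's signed effect (positive for CpGs
    hypermethylated in smokers) and its never-smoker baseline beta equals
    the panel's reference beta.
    """
    signed = np.where(panel["direction"].values == HYPER,
                      panel["effect_size"].values,
                      -panel["effect_size"].values)
    return replace(config,
                   n_signal_cpgs=len(panel),
                   effect_sizes=tuple(signed),
                   signal_baselines=tuple(panel["reference_beta"].values))


def write_cohort(out_dir, beta: pd.DataFrame, sheet: pd.DataFrame,
                 detection_p: pd.DataFrame, truth: GroundTruth,
                 manifest: pd.DataFrame) -> None:
    """Write a cohort to disk: beta/detection TSV, sheet + manifest CSV,
    ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta.to_csv(out / "beta.tsv", sep="\t", index_label="probe_id")
    detection_p.to_csv(out / "detection_p.tsv", sep="\t", index_label="probe_id")
    sheet.to_csv(out / "sample_sheet.csv", index=False)
    manifest.to_csv(out / "manifest.csv", index=False)
    truth.to_json(out / "ground_truth.json")
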