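"""Quality control and scale transformations for methylation-array data.

Implements the pre-analysis contract of a typical 450k-style workflow:
detection-p based sample and probe filtering, exclusion of multi-homology
probes, the beta <-> M (logit2) transformation used to variance-stabilise
methylation fractions before linear modelling, and a per-chip batch
centering step.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "QcReport",
    "beta_to_m",
    "m_to_beta",
    "filter_samples",
    "filter_probes",
    "batch_center",
    "run_qc",
]


@dataclass
class QcReport:
    """Counts and identities of probes/samples removed during QC.

    A probe failing both the detection and the homology rule is counted
    once, under detection (the detection filter is applied first).
    """

    probes_removed_detection: int = 0
    probes_removed_homology: int = 0
    samples_removed: int = 0
    surviving_probes: list = field(default_factory=list)
    surviving_samples: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _check_beta_domain(values: np.ndarray) -> None:
    if not np.all((values > 0.0) & (values < 1.0)):
        bad = values[~((values > 0.0) & (values < 1.0))]
        raise ValueError(
            f"beta values must lie strictly in (0, 1); found e.g. {bad.flat[0]!r}"
        )


def beta_to_m(beta):
    """Logit2 transform: M = log2(beta / (1 - beta)).

    Accepts scalars, arrays, Series or DataFrames and preserves the
    container type. Values outside the open interval (0, 1) raise a
    ValueError -- there is no silent clipping.
    """
    values = np.asarray(beta, dtype=float)
    _check_beta_domain(values)
    m = np.log2(values) - np.log2(1.0 - values)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2 transform: beta = 1 / (1 + 2**(-M))."""
    values = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-values))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(beta)
    return beta


def filter_samples(detection_p: pd.DataFrame, threshold_fraction: float = 0.95,
                   detection_alpha: float = 0.01) -> list:
    """Samples surviving detection QC.

    A sample is kept when strictly more than ``threshold_fraction`` of its
    probes have detection p-value below ``detection_alpha``.

    Parameters
    ----------
    detection_p : DataFrame, probes x samples.
    """
    detected = (detection_p.values < detection_alpha).mean(axis=0)
    keep = detected > threshold_fraction
    if not keep.any():
        raise ValueError("all samples failed QC (no sample exceeds the "
                         f"{threshold_fraction:.0%} detection fraction)")
    return [s for s, k in zip(detection_p.columns, keep) if k]


def filter_probes(detection_p: pd.DataFrame, homology_flags: pd.Series,
                  threshold_fraction: float = 0.95,
                  detection_alpha: float = 0.01):
    """Probes surviving detection QC and the multi-homology exclusion.

    Probes detected (p < ``detection_alpha``) in fewer than
    ``threshold_fraction`` of samples are removed first; homology-flagged
    probes are removed second, so a probe failing both rules is counted
    under detection.

    Returns
    -------
    (surviving_probe_ids, QcReport)
    """
    flags = homology_flags.reindex(detection_p.index)
    if flags.isna().any():
        missing = flags.index[flags.isna()][:3].tolist()
        raise ValueError(f"homology flags missing for probes {missing}")
    detected = (detection_p.values < detection_alpha).mean(axis=1)
    fail_detect = detected < threshold_fraction
    fail_homology = flags.values.astype(bool) & ~fail_detect
    keep = ~(fail_detect | flags.values.astype(bool))
    surviving = [p for p, k in zip(detection_p.index, keep) if k]
    report = QcReport(
        probes_removed_detection=int(fail_detect.sum()),
        probes_removed_homology=int(fail_homology.sum()),
        samples_removed=0,
        surviving_probes=surviving,
        surviving_samples=list(detection_p.columns),
    )
    return surviving, report


def batch_center(m_matrix: pd.DataFrame, chip_ids) -> pd.DataFrame:
    """Remove per-chip (batch) offsets from an M-value matrix.

    For every probe, each sample's value has its chip mean subtracted and
    the probe's grand mean added back, so between-chip mean differences are
    removed while the probe-level grand mean is preserved. A chip with a
    single sample is centered onto the grand mean (a warning is emitted,
    since nothing can be learned about its offset).
    """
    chips = pd.Series(np.asarray(chip_ids), index=m_matrix.columns)
    if chips.isna().any():
        raise ValueError("every sample needs a chip id")
    counts = chips.value_counts()
    singletons = counts[counts == 1]
    if len(singletons):
        warnings.warn(
            f"chip(s) {singletons.index.tolist()} contain a single sample; "
            "their values are centered onto the probe grand mean",
            stacklevel=2,
        )
    values = m_matrix.values
    grand = values.mean(axis=1, keepdims=True)
    out = np.empty_like(values)
    for chip in counts.index:
        cols = (chips == chip).values
        chip_mean = values[:, cols].mean(axis=1, keepdims=True)
        out[:, cols] = values[:, cols] - chip_mean + grand
    return pd.DataFrame(out, index=m_matrix.index, columns=m_matrix.columns)


def run_qc(beta: pd.DataFrame, detection_p: pd.DataFrame, manifest: pd.DataFrame,
           threshold_fraction: float = 0.95, detection_alpha: float = 0.01):
    """Full QC pass: sample filter, then probe filters on surviving samples.

    Returns the filtered beta matrix and a combined :class:`QcReport`.
    ``manifest`` must carry a boolean ``homology`` column indexed by probe.
    """
    samples = filter_samples(detection_p, threshold_fraction, detection_alpha)
    detp = detection_p[samples]
    flags = manifest.set_index("probe_id")["homology"] if "probe_id" in manifest.columns \
        else manifest["homology"]
    probes, report = filter_probes(detp, flags, threshold_fraction, detection_alpha)
    report.samples_removed = beta.shape[1] - len(samples)
    report.surviving_samples = samples
    return beta.loc[probes, samples], report
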