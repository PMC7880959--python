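"""Sample-level agreement metrics for eye-movement classifications.

These are the standard measures for comparing an algorithmic labeling
against human raters (or two raters against each other) on a per-sample
basis: misclassification proportion, per-category Jaccard indices,
Cohen's kappa, and a scalar event-duration-statistics RMSD.

Before any comparison, the classifier's fine-grained labels are collapsed
to the four-category vocabulary used in comparison studies: SACC/ISAC ->
SACC, and all four PSO sub-labels -> PSO.  Samples labeled blink or
undefined by either sequence are conventionally excluded by restricting
``include_labels``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPARISON_LABELS", "collapse_labels", "misclassification", "jaccard",
    "jaccard_matrix", "cohens_kappa", "AgreementReport", "agreement_report",
    "duration_stats_rmsd", "events_to_samples",
    "read_label_samples", "write_label_samples",
]

#: Default comparison vocabulary.
COMPARISON_LABELS = ("FIXA", "SACC", "PSO", "PURS")

_COLLAPSE = {
    "ISAC": "SACC",
    "HPSO": "PSO", "IHPS": "PSO", "LPSO": "PSO", "ILPS": "PSO",
}


class UndefinedMetricError(ValueError):
    """The metric is undefined for these inputs."""


def collapse_labels(seq: Sequence[str]) -> np.ndarray:
    """Collapse saccade and PSO sub-labels into single categories."""
    a = np.asarray(seq, dtype="U8")
    out = a.copy()
    for src, dst in _COLLAPSE.items():
        out[a == src] = dst
    return out


def _paired(a: Sequence[str], b: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    a = collapse_labels(a)
    b = collapse_labels(b)
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length "
                         f"({len(a)} vs {len(b)})")
    return a, b


def misclassification(a: Sequence[str], b: Sequence[str],
                      include_labels: Iterable[str] = COMPARISON_LABELS
                      ) -> float:
    """Proportion of disagreeing samples.

    The universe is every sample where *either* sequence assigns an
    included label; within it, the fraction with differing labels.
    Samples where only one sequence assigns an included label therefore
    count as disagreements.
    """
    a, b = _paired(a, b)
    include = np.asarray(list(include_labels), dtype="U8")
    universe = np.isin(a, include) | np.isin(b, include)
    if not universe.any():
        raise UndefinedMetricError("no samples carry an included label")
    return float(np.mean(a[universe] != b[universe]))


def jaccard(a: Sequence[str], b: Sequence[str], category: str) -> float:
    """Jaccard index of one category: |both| / |either|.

    By convention 1.0 when the category is absent from both sequences
    (flagged with a warning).
    """
    a, b = _paired(a, b)
    in_a = a == category
    in_b = b == category
    either = int(np.sum(in_a | in_b))
    if either == 0:
        warnings.warn(f"category {category!r} absent from both sequences; "
                      "Jaccard index is 1.0 by convention", UserWarning,
                      stacklevel=2)
        return 1.0
    return float(np.sum(in_a & in_b) / either)


def jaccard_matrix(a: Sequence[str], b: Sequence[str],
                   labels: Iterable[str] = COMPARISON_LABELS) -> pd.DataFrame:
    """Per-label-pair Jaccard confusion matrix.

    Entry (i, j) is |a==i and b==j| / |a==i or b==j|; the diagonal is the
    per-category agreement of the two sequences.
    """
    a, b = _paired(a, b)
    labels = list(labels)
    m = np.zeros((len(labels), len(labels)))
    for i, li in enumerate(labels):
        in_a = a == li
        for j, lj in enumerate(labels):
            in_b = b == lj
            either = int(np.sum(in_a | in_b))
            m[i, j] = np.sum(in_a & in_b) / either if either else np.nan
    return pd.DataFrame(m, index=labels, columns=labels)


def cohens_kappa(a: Sequence[str], b: Sequence[str]) -> float:
    """Chance-corrected sample-by-sample agreement,

        K = (P_o - P_c) / (1 - P_c),

    with observed agreement P_o and chance agreement P_c from the two
    sequences' marginal label frequencies.  K = 1 is perfect agreement,
    K = 0 chance-level agreement.
    """
    a, b = _paired(a, b)
    n = len(a)
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    p_c = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if p_c >= 1.0:
        raise UndefinedMetricError(
            "chance agreement is 1 (both sequences constant and equal); "
            "kappa is undefined")
    return (p_o - p_c) / (1.0 - p_c)


@dataclass
class AgreementReport:
    """Bundle of the sample-level agreement measures of two labelings."""

    misclassification: float
    confusion: pd.DataFrame
    kappa: float


def agreement_report(a: Sequence[str], b: Sequence[str],
                     include_labels: Iterable[str] = COMPARISON_LABELS
                     ) -> AgreementReport:
    """Misclassification, Jaccard confusion and kappa over the samples
    where either sequence assigns an included label."""
    ac, bc = _paired(a, b)
    include = np.asarray(list(include_labels), dtype="U8")
    universe = np.isin(ac, include) | np.isin(bc, include)
    if not universe.any():
        raise UndefinedMetricError("no samples carry an included label")
    au, bu = ac[universe], bc[universe]
    return AgreementReport(
        misclassification=float(np.mean(au != bu)),
        confusion=jaccard_matrix(au, bu, include_labels),
        kappa=cohens_kappa(au, bu),
    )


# ---------------------------------------------------------------------------
# event-duration statistics

def _label_durations(events) -> pd.DataFrame:
    """Normalize an event collection to a (label, duration) frame.

    Accepts a pandas DataFrame with label/duration columns, classified
    GazeEvent objects, or (label, duration) pairs.
    """
    if isinstance(events, pd.DataFrame):
        df = events[["label", "duration"]].copy()
    else:
        rows = []
        for e in events:
            if hasattr(e, "label") and hasattr(e, "duration"):
                rows.append((e.label, e.duration))
            else:
                lab, dur = e
                rows.append((lab, dur))
        df = pd.DataFrame(rows, columns=["label", "duration"])
    df["label"] = collapse_labels(df["label"].to_numpy())
    return df


def _duration_stats(df: pd.DataFrame, label: str) -> np.ndarray:
    durs = df.loc[df["label"] == label, "duration"].to_numpy(dtype=float)
    if durs.size == 0:
        return np.array([np.nan, np.nan, 0.0])
    return np.array([float(np.mean(durs)), float(np.std(durs)),
                     float(durs.size)])


def duration_stats_rmsd(candidate_events, rater1_events, rater2_events,
                        labels: Iterable[str] | None = None,
                        normalization: str = "max") -> dict[str, float]:
    """Distribution dissimilarity of event durations per event type.

    For each event type the characteristic vector (mean duration, SD of
    durations, event count) is computed for the candidate and for the
    average of the two raters.  With the default ``normalization="max"``
    each characteristic is scaled by its maximum across the three
    entities (candidate and both raters) before the root-mean-square
    deviation is taken; ``normalization="none"`` compares raw values.
    0.0 means the candidate matches the rater average exactly; event
    types missing from a list are flagged and scored on the available
    characteristics.
    """
    if normalization not in ("max", "none"):
        raise ValueError("normalization must be 'max' or 'none'")
    cand = _label_durations(candidate_events)
    r1 = _label_durations(rater1_events)
    r2 = _label_durations(rater2_events)
    if labels is None:
        labels = sorted(set(cand["label"]) | set(r1["label"])
                        | set(r2["label"]))
    scores: dict[str, float] = {}
    for lab in labels:
        sc = _duration_stats(cand, lab)
        s1 = _duration_stats(r1, lab)
        s2 = _duration_stats(r2, lab)
        avg = (s1 + s2) / 2.0
        ok = np.isfinite(sc) & np.isfinite(avg)
        if not ok.all():
            warnings.warn(f"event type {lab!r} missing from one of the "
                          "event lists; RMSD computed on the available "
                          "characteristics", UserWarning, stacklevel=2)
        if not ok.any():
            scores[lab] = np.nan
            continue
        c, av = sc[ok], avg[ok]
        if normalization == "max":
            scale = np.nanmax(np.vstack([sc, s1, s2]), axis=0)[ok]
            # guard degenerate characteristics (zero up to rounding)
            scale = np.where(scale > 1e-9, scale, 1.0)
            c = c / scale
            av = av / scale
        scores[lab] = float(np.sqrt(np.mean((c - av) ** 2)))
    return scores


# ---------------------------------------------------------------------------
# label-sample file dialect and sample expansion

def events_to_samples(events, n_samples: int, sampling_rate: float,
                      fill: str = "NONE") -> np.ndarray:
    """Expand an event list into a per-sample label sequence.

    Accepts classified GazeEvent objects or (label, onset_s, offset_s)
    tuples; later events overwrite earlier ones where they overlap.
    """
    labels = np.full(n_samples, fill, dtype="U8")
    for e in events:
        if hasattr(e, "label"):
            lab, on, off = e.label, e.onset_time, e.offset_time
        else:
            lab, on, off = e
        a = max(0, int(round(on * sampling_rate)))
        b = min(n_samples, int(round(off * sampling_rate)))
        labels[a:b] = lab
    return labels


def read_label_samples(path) -> np.ndarray:
    """Read a per-sample label file (TSV: sample index, label)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["index", "label"])
    out = np.full(int(df["index"].max()) + 1, "NONE", dtype="U8")
    out[df["index"].to_numpy()] = df["label"].to_numpy(dtype="U8")
    return out


def write_label_samples(labels: Sequence[str], path) -> None:
    """Write per-sample labels (TSV: sample index, label)."""
    with open(path, "w") as f:
        for i, lab in enumerate(labels):
            f.write(f"{i}\t{lab}\n")
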