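#!/usr/bin/env python
"""Compare the classifier with hand-labeled gaze data (user-supplied).

Runs the classifier with default parameters on a directory of gaze
recordings that come with per-sample expert labels, and reports the
misclassification proportion, the per-category Jaccard confusion matrix
and Cohen's kappa against each rater.

This needs an external dataset download (gaze TSVs plus per-sample label
TSVs in the dialects documented in the package README); nothing is
bundled.  Expected layout, one recording per basename:

    <data_dir>/<name>_gaze.tsv          X/Y gaze samples, tab-separated
    <data_dir>/<name>_labels_<rater>.tsv   per-sample labels (index, label)

Labels are compared over the four-category vocabulary (fixation,
saccade, PSO, pursuit) after collapsing sub-labels; samples labeled
otherwise (blink, undefined) by a rater are excluded from that
comparison by the metric's universe rule.

Usage:
    python scripts/compare_with_hand_labels.py <data_dir> \
        --px2deg 0.0185 --sampling-rate 500
"""

import argparse
from collections import defaultdict
from pathlib import Path

from gazevents import classify_recording, read_gaze
from gazevents.metrics import (agreement_report, events_to_samples,
                               read_label_samples)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("data_dir", type=Path)
    parser.add_argument("--px2deg", type=float, required=True)
    parser.add_argument("--sampling-rate", type=float, required=True)
    args = parser.parse_args()

    recordings = sorted(args.data_dir.glob("*_gaze.tsv"))
    if not recordings:
        raise SystemExit(f"no *_gaze.tsv recordings in {args.data_dir}")
    by_rater = defaultdict(list)
    for gaze_path in recordings:
        name = gaze_path.name[:-len("_gaze.tsv")]
        series = read_gaze(gaze_path, args.px2deg, args.sampling_rate)
        events = classify_recording(series)
        predicted = events_to_samples(events, series.n_samples,
                                      series.sampling_rate)
        for label_path in sorted(args.data_dir.glob(
                f"{name}_labels_*.tsv")):
            rater = label_path.stem.split("_labels_")[-1]
            rated = read_label_samples(label_path)
            m = min(len(rated), len(predicted))
            rep = agreement_report(rated[:m], predicted[:m])
            by_rater[rater].append((name, rep))

    for rater, reports in by_rater.items():
        print(f"\n=== classifier vs rater {rater} ===")
        for name, rep in reports:
            print(f"{name}: misclassification={rep.misclassification:.3f} "
                  f"kappa={rep.kappa:.3f}")
            print(rep.confusion.round(3))


if __name__ == "__main__":
    main()
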