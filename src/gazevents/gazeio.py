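"""File I/O, command-line interface and diagnostic visualization.

Input: headerless tab-separated text with one gaze sample per line; the
first two columns are X and Y screen coordinates in pixels, further
columns are ignored, and any non-numeric token marks a missing sample.

Output: a BIDS-style events table (tab-separated, header line, onset and
duration in seconds) with one classified event per line, plus an optional
diagnostic figure of the classified recording.
"""

from __future__ import annotations

import argparse
import logging
import sys
import warnings
from dataclasses import fields

import numpy as np
import pandas as pd

from .classify import ClassifierParams, GazeEvent, classify_recording
from .preprocess import (GazeSeries, PreprocessParams, VelocitySeries,
                         preprocess)
from .threshold import ThresholdParams

__all__ = [
    "read_gaze", "write_gaze", "read_events", "write_events",
    "render_diagnostics", "run_cli", "main", "EVENT_COLUMNS",
]

log = logging.getLogger("gazevents")

#: Serialized event table columns (onset/duration in s, coordinates px,
#: amp in deg, velocities in deg/s).
EVENT_COLUMNS = ("onset", "duration", "label", "start_x", "start_y",
                 "end_x", "end_y", "amp", "peak_vel", "med_vel", "avg_vel")

#: Colors of the per-label shading in diagnostic plots.
LABEL_COLORS = {
    "FIXA": "#2ca02c",
    "PURS": "#d2b48c",
    "SACC": "#1f77b4",
    "ISAC": "#17becf",
    "HPSO": "#4b0082",
    "IHPS": "#6a0dad",
    "LPSO": "#c8a2c8",
    "ILPS": "#dda0dd",
}


def read_gaze(path, px2deg: float, sampling_rate: float,
              skip_header: bool = False) -> GazeSeries:
    """Read a tab-separated gaze coordinate file.

    Only the first two columns are read and interpreted as X and Y pixel
    coordinates; any non-numeric token becomes a missing sample.  A line
    with fewer than two columns raises a parse error naming the line.
    """
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            if skip_header and lineno == 1:
                continue
            line = line.rstrip("\n\r")
            if not line and lineno > 1:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 2 tab-"
                    f"separated columns, found {len(parts)}")
            vals = []
            for tok in parts[:2]:
                try:
                    v = float(tok)
                except ValueError:
                    v = np.nan
                vals.append(v if np.isfinite(v) else np.nan)
            xs.append(vals[0])
            ys.append(vals[1])
    if not xs:
        raise ValueError(f"{path}: empty gaze file")
    return GazeSeries(np.array(xs), np.array(ys), sampling_rate, px2deg)


def write_gaze(series: GazeSeries, path) -> None:
    """Write a gaze series in the input dialect (X TAB Y, NaN for missing)."""
    with open(path, "w") as f:
        for x, y in zip(series.x, series.y):
            xs = f"{x:.3f}" if np.isfinite(x) else "nan"
            ys = f"{y:.3f}" if np.isfinite(y) else "nan"
            f.write(f"{xs}\t{ys}\n")


def events_to_frame(events: list[GazeEvent]) -> pd.DataFrame:
    """Events as a data frame in the serialized column layout."""
    return pd.DataFrame(
        [{
            "onset": e.onset_time,
            "duration": e.duration,
            "label": e.label,
            "start_x": e.start_x, "start_y": e.start_y,
            "end_x": e.end_x, "end_y": e.end_y,
            "amp": e.amplitude,
            "peak_vel": e.peak_vel,
            "med_vel": e.median_vel,
            "avg_vel": e.avg_vel,
        } for e in events],
        columns=list(EVENT_COLUMNS))


def write_events(events: list[GazeEvent], path) -> None:
    """Write a BIDS-style events table: tab-separated, header line, one
    event per line, onset and duration in seconds.

    Numeric serialization is fixed-precision (3 decimals for seconds, px
    and deg; 2 for velocities) so repeated runs produce byte-identical
    files.
    """
    df = events_to_frame(events)
    for col in ("onset", "duration", "start_x", "start_y", "end_x", "end_y",
                "amp"):
        df[col] = df[col].map(lambda v: f"{v:.3f}")
    for col in ("peak_vel", "med_vel", "avg_vel"):
        df[col] = df[col].map(lambda v: f"{v:.2f}")
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read an events table written by :func:`write_events`."""
    return pd.read_csv(path, sep="\t")


def render_diagnostics(series: GazeSeries, velocities: VelocitySeries,
                       events: list[GazeEvent], path) -> None:
    """Plot coordinates and velocity with per-label event shading.

    Every label present in ``events`` appears in the legend.  Plotting
    problems degrade to a warning, never an error.
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = np.arange(series.n_samples) / series.sampling_rate
        fig, ax = plt.subplots(figsize=(max(8, series.duration * 0.8), 4))
        seen = []
        for e in events:
            color = LABEL_COLORS.get(e.label, "#aaaaaa")
            ax.axvspan(e.onset_time, e.offset_time, color=color, alpha=0.35,
                       label=e.label if e.label not in seen else None)
            if e.label not in seen:
                seen.append(e.label)
        ax.plot(t, series.x, color="black", lw=0.6, label="x (px)")
        ax.plot(t, series.y, color="0.3", lw=0.6, label="y (px)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("gaze position (px)")
        ax2 = ax.twinx()
        ax2.plot(t, velocities.v, color="gray", lw=0.4, alpha=0.8)
        ax2.set_ylabel("velocity (deg/s)", color="gray")
        ax.legend(loc="upper right", fontsize="x-small", ncol=2)
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
    except Exception as exc:  # diagnostics must never break classification
        warnings.warn(f"diagnostic figure could not be rendered: {exc}",
                      UserWarning, stacklevel=2)


# ---------------------------------------------------------------------------
# command line interface

def _add_param_args(parser: argparse.ArgumentParser) -> None:
    """One long flag per classifier/preprocessing/threshold parameter."""
    groups = (
        ("preprocessing", PreprocessParams),
        ("threshold estimation", ThresholdParams),
        ("event classification", ClassifierParams),
    )
    for title, cls in groups:
        g = parser.add_argument_group(title)
        for f in fields(cls):
            if f.name in ("preprocess", "threshold"):
                continue
            default = f.default
            typ = int if f.name == "savgol_polyord" else float
            g.add_argument(f"--{f.name.replace('_', '-')}", type=typ,
                           default=default, metavar="X",
                           help=f"default: {default}")


def _params_from_args(args: argparse.Namespace) -> ClassifierParams:
    pp = PreprocessParams(**{f.name: getattr(args, f.name)
                             for f in fields(PreprocessParams)})
    tp = ThresholdParams(**{f.name: getattr(args, f.name)
                            for f in fields(ThresholdParams)})
    cp = {f.name: getattr(args, f.name) for f in fields(ClassifierParams)
          if f.name not in ("preprocess", "threshold")}
    return ClassifierParams(preprocess=pp, threshold=tp, **cp)


def run_cli(argv: list[str] | None = None) -> int:
    """Classify one recording from the command line.

    Usage: gazevents <infile> <outfile> <px2deg> <sampling_rate> [options]

    Writes the events table to <outfile> and a diagnostic figure to
    <outfile>.png; returns the process exit status.
    """
    parser = argparse.ArgumentParser(
        prog="gazevents",
        description="Adaptive velocity-based eye-movement event "
                    "classification of a gaze coordinate recording.")
    parser.add_argument("infile", help="tab-separated gaze coordinate file")
    parser.add_argument("outfile", help="output events table (TSV)")
    parser.add_argument("px2deg", type=float,
                        help="visual degrees per (square) pixel")
    parser.add_argument("sampling_rate", type=float,
                        help="sampling rate in Hz")
    parser.add_argument("--skip-header", action="store_true",
                        help="ignore the first input line")
    parser.add_argument("--no-figure", action="store_true",
                        help="do not render the diagnostic figure")
    _add_param_args(parser)
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)

    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s: %(message)s")
    try:
        params = _params_from_args(args)
        log.info("parameters: %s", params)
        series = read_gaze(args.infile, args.px2deg, args.sampling_rate,
                           skip_header=args.skip_header)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            events = classify_recording(series, params)
            for w in caught:
                log.warning("%s", w.message)
        write_events(events, args.outfile)
        log.info("wrote %d events to %s", len(events), args.outfile)
        if not args.no_figure:
            streams = preprocess(series, params.preprocess)
            render_diagnostics(streams.series, streams.velocity, events,
                               f"{args.outfile}.png")
    except Exception as exc:
        log.error("%s", exc)
        return 1
    return 0


def main() -> None:
    sys.exit(run_cli())
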