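"""End-to-end pipeline: read tracks, normalize, fit covariance, run tests.

The layout file is a TSV with columns (condition, factor, replicate, path);
tracks may be bedGraph or bigWig.  Outputs are plain text: the normalized
signal matrix, the fitted covariance model as JSON, a per-window statistics
TSV, BED6+ files for occupancy / differential / condition-specific regions,
and a JSON run log echoing configuration and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariance import CovarianceModel
from .layout import TrackLayout
from .lrt import merge_contiguous_windows, run_cascade
from .normalize import SignalMatrix, normalize_signal
from .windows import (GenomeWindows, bin_bedgraph, bin_bigwig, read_bed3,
                      read_chrom_sizes, tile_genome)

logger = logging.getLogger("dcap")

__all__ = ["RunConfig", "run_full", "read_layout", "load_tracks"]


@dataclass
class RunConfig:
    """Declarative configuration of a full run; defaults are the method's
    standard settings (1-kb windows, 0.1 pseudocount, span-0.5 local-linear
    LOESS on a 1%/25-bin subsample, +-5 kb background, alpha 0.05 with
    Bonferroni correction)."""

    layout_path: str = ""
    chrom_sizes_path: str = ""
    regions_path: str = ""          # explicit test regions (peaks mode input)
    blacklist_path: str = ""
    out_dir: str = "dcap_out"
    window_width: int = 1000
    pseudocount: float = 0.1
    span: float = 0.5
    loess_degree: int = 1
    sample_frac: float = 0.01
    n_bins: int = 25
    min_points: int = 300
    halfspan: int = 5000
    alpha: float = 0.05
    correction: str = "bonferroni"
    enriched_only: bool = False
    peaks_mode: bool = False
    test3_family: str = "genome"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def read_layout(path: str | Path) -> tuple[TrackLayout, pd.DataFrame]:
    """Read the (condition, factor, replicate, path) layout TSV.

    Returns the TrackLayout and the table sorted into canonical column order;
    errors name the offending (condition, factor, replicate) combination.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"condition", "factor", "replicate", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"layout file must have columns {sorted(required)}")
    conditions = list(dict.fromkeys(df["condition"]))
    factors = list(dict.fromkeys(df["factor"]))
    reps = sorted(df["replicate"].astype(int).unique())
    R = len(reps)
    layout = TrackLayout(conditions, factors, R)
    rows = []
    for c in conditions:
        for f in factors:
            for r in reps:
                sel = df[(df["condition"] == c) & (df["factor"] == f)
                         & (df["replicate"].astype(int) == r)]
                if len(sel) != 1:
                    raise ValueError(
                        f"layout needs exactly one track for condition={c} "
                        f"factor={f} replicate={r}, found {len(sel)}"
                    )
                rows.append(sel.iloc[0])
    ordered = pd.DataFrame(rows).reset_index(drop=True)
    if len(ordered) != layout.n_tracks:
        raise ValueError(
            f"track count {len(ordered)} != C*K*R = {layout.n_tracks}"
        )
    # relative track paths resolve against the layout file's directory
    base = Path(path).parent
    ordered["path"] = [p if Path(p).is_absolute() else str(base / p)
                       for p in ordered["path"]]
    return layout, ordered


def load_tracks(ordered: pd.DataFrame, windows: GenomeWindows) -> np.ndarray:
    """Bin every track in layout order into the window grid."""
    cols = []
    for rec in ordered.itertuples(index=False):
        path = str(rec.path)
        if path.endswith((".bw", ".bigwig", ".bigWig")):
            cols.append(bin_bigwig(path, windows))
        else:
            cols.append(bin_bedgraph(path, windows))
    return np.column_stack(cols)


def run_full(config: RunConfig) -> Path:
    """Execute the whole pipeline and write all artifacts to ``out_dir``."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout, ordered = read_layout(config.layout_path)
    logger.info("layout: C=%d K=%d R=%d", layout.n_conditions,
                layout.n_factors, layout.n_replicates)

    if config.peaks_mode and config.regions_path:
        regions = read_bed3(config.regions_path)
        windows = GenomeWindows.from_regions(regions, config.window_width)
    else:
        sizes = read_chrom_sizes(config.chrom_sizes_path)
        blacklist = read_bed3(config.blacklist_path) if config.blacklist_path else None
        windows = tile_genome(sizes, config.window_width, blacklist)
    logger.info("windows: %d", len(windows))

    raw = load_tracks(ordered, windows)
    signal = SignalMatrix(windows, raw, layout, stage="raw")
    norm = normalize_signal(
        signal, pseudocount=config.pseudocount, span=config.span,
        sample_frac=config.sample_frac, n_bins=config.n_bins,
        seed=config.seed, min_points=config.min_points,
    )
    norm.write_tsv(out / "normalized_signal.tsv")
    logger.info("normalization done (%.1fs)", time.time() - t0)

    model = CovarianceModel(
        layout, mode="peaks" if config.peaks_mode else "background",
        span=config.span, sample_frac=config.sample_frac,
        n_bins=config.n_bins, min_points=config.min_points, seed=config.seed,
    ).fit(norm.values)
    model.save(out / "covariance_model.json")

    results = run_cascade(
        norm, model, alpha=config.alpha, correction=config.correction,
        enriched_only=config.enriched_only, peaks_mode=config.peaks_mode,
        halfspan=config.halfspan, test3_family=config.test3_family,
    )
    results.to_csv(out / "window_statistics.tsv", sep="\t", index=False,
                   float_format="%.6g")

    _write_beds(results, out, config.peaks_mode)
    log = {
        "version": __version__,
        "config": asdict(config),
        "n_windows": len(windows),
        "n_bound": int(results["bound"].sum()),
        "n_differential": int(results["differential"].sum()),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    logger.info("run complete (%.1fs)", time.time() - t0)
    return out


def _bed_score(p_adj: pd.Series) -> np.ndarray:
    with np.errstate(divide="ignore"):
        s = -np.log10(np.maximum(p_adj.to_numpy(dtype=float), 1e-300))
    return np.minimum(np.nan_to_num(s), 1000.0)


def _write_beds(results: pd.DataFrame, out: Path, peaks_mode: bool) -> None:
    def write(df, name_col, score, path):
        bed = pd.DataFrame({
            "chrom": df["chrom"], "start": df["start"], "end": df["end"],
            "name": name_col, "score": np.round(score, 3), "strand": ".",
        })
        bed.to_csv(path, sep="\t", index=False, header=False)

    if not peaks_mode:
        b = results[results["bound"]]
        write(b, "occupancy", _bed_score(b["p1_adj"]), out / "occupancy.bed")
    d = results[results["differential"]]
    write(d, "differential", _bed_score(d["p2_adj"]), out / "differential.bed")
    s = d[~d["label"].isin(["none", "unclassified", ""])]
    if len(s):
        write(s, s["label"], _bed_score(s["p2_adj"]), out / "condition_specific.bed")
        merged = merge_contiguous_windows(s[["chrom", "start", "end", "label"]])
        merged.to_csv(out / "condition_specific_merged.bed", sep="\t",
                      index=False, header=False)
    else:
        (out / "condition_specific.bed").write_text("")
        (out / "condition_specific_merged.bed").write_text("")
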