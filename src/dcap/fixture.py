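"""Desk-scale synthetic fixture: a toy genome with planted peaks.

Writes a two-chromosome genome (1,000 x 1-kb windows), bedGraph tracks for a
3-condition x 2-factor x 2-replicate layout with planted common,
differential and condition-specific peaks, plus a truth BED.  Synthetic
stand-in for consortium-scale input; exercises every pipeline stage quickly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .layout import TrackLayout

__all__ = ["make_fixture", "FIXTURE_CHROMS"]

FIXTURE_CHROMS = {"chrA": 600_000, "chrB": 400_000}
_WIDTH = 1000


def make_fixture(seed: int = 0, out_dir: str | Path = "fixture") -> Path:
    """Write the fixture dataset; fully determined by ``seed``.

    Planted truth (on the log2 scale, background level ~5, bound level ~9):

    * 30 windows bound in all 3 conditions ("common");
    * 15 windows bound in exactly 2 conditions (differential; the odd one
      out — the unbound condition — is the expected specificity label);
    * 15 windows bound in exactly 1 condition (differential; that condition
      is the expected label).

    ``truth.bed`` columns: chrom, start, end, category(common/differential),
    expected label ('.' for common).
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = TrackLayout(["c1", "c2", "c3"], ["f1", "f2"], 2)
    C, P = layout.n_conditions, layout.tracks_per_condition

    chrom_list, start_list = [], []
    for chrom, size in FIXTURE_CHROMS.items():
        s = np.arange(0, size, _WIDTH)
        chrom_list.extend([chrom] * len(s))
        start_list.append(s)
    starts = np.concatenate(start_list)
    chroms = np.asarray(chrom_list)
    N = len(starts)

    # background log2 level with a gentle intensity trend for the LOESS step
    base = rng.normal(5.0, 0.8, size=N)
    log2sig = base[:, None] + rng.normal(0.0, 0.7, size=(N, C * P))

    picks = rng.choice(N, size=60, replace=False)
    common, diff2, diff1 = picks[:30], picks[30:45], picks[45:]
    bound = np.zeros((N, C), dtype=bool)
    bound[common] = True
    truth_rows = []
    for w in common:
        truth_rows.append((chroms[w], starts[w], "common", "."))
    for w in diff2:
        off = int(rng.integers(C))          # the single unbound condition
        bound[w] = True
        bound[w, off] = False
        truth_rows.append((chroms[w], starts[w], "differential", layout.conditions[off]))
    for w in diff1:
        on = int(rng.integers(C))
        bound[w, on] = True
        truth_rows.append((chroms[w], starts[w], "differential", layout.conditions[on]))

    for j in range(C):
        rows = np.flatnonzero(bound[:, j])
        sl = layout.condition_slice(j)
        log2sig[rows, sl] = 9.0 + rng.normal(0.0, 0.4, size=(len(rows), P))

    # write bedGraph tracks: per-bp density so the window sum is 2^log2sig
    layout_rows = []
    for t, name in enumerate(layout.track_names):
        cond, factor, rep = name.split(".")
        path = out / f"{name}.bedgraph"
        density = (2.0 ** log2sig[:, t]) / _WIDTH
        df = pd.DataFrame({
            "chrom": chroms, "start": starts, "end": starts + _WIDTH,
            "value": np.round(density, 6),
        })
        for chrom, size in FIXTURE_CHROMS.items():
            df.loc[df["chrom"] == chrom, "end"] = np.minimum(
                df.loc[df["chrom"] == chrom, "end"], size)
        df.to_csv(path, sep="\t", index=False, header=False)
        # bare filenames keep the fixture relocatable; the layout reader
        # resolves them against the layout file's directory
        layout_rows.append({"condition": cond, "factor": factor,
                            "replicate": rep.removeprefix("rep"),
                            "path": path.name})

    pd.DataFrame(layout_rows).to_csv(out / "layout.tsv", sep="\t", index=False)
    with open(out / "chrom.sizes", "w") as fh:
        for chrom, size in FIXTURE_CHROMS.items():
            fh.write(f"{chrom}\t{size}\n")
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "category", "label"])
    truth["end"] = truth["start"] + _WIDTH
    truth = truth[["chrom", "start", "end", "category", "label"]].sort_values(
        ["chrom", "start"])
    truth.to_csv(out / "truth.bed", sep="\t", index=False, header=False)
    return out
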