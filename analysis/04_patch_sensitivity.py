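#!/usr/bin/env python
"""Patch-seeded sensitivity: signal loss of ear montages relative to the cap.

Each of the 50 left-lateral cortex patches is activated coherently (1 nA*m
per vertex along the outward normals); for every montage the exhaustive
best bipolar pair defines the recorded amplitude, and the percentage loss
is taken relative to the best cap pair.  The winning-pair histogram is
accumulated over patches with below-average loss.  Tables go to
results/patch_sensitivity/.
"""

from pathlib import Path

import pandas as pd

from earfield.cli import load_head
from earfield.io import read_leadfield
from earfield.scenarios import DEFAULT_BIPOLAR_CHANNELS
from earfield.sensitivity import (
    best_pair_histogram,
    run_patch_analysis,
    summarize_losses,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    head = load_head(ROOT / "head")
    lf_cap = read_leadfield(ROOT / "leadfields" / "cap.tsv")
    lf_ear = read_leadfield(ROOT / "leadfields" / "ear_bilateral.tsv")
    out = ROOT / "patch_sensitivity"
    out.mkdir(parents=True, exist_ok=True)

    table = run_patch_analysis(
        lf_cap, lf_ear, head.parcellation, DEFAULT_BIPOLAR_CHANNELS
    )
    summary = summarize_losses(table)
    hist = best_pair_histogram(table, head.ear_montage)

    table.drop(columns=["ear_pair_idx"]).to_csv(
        out / "patches.tsv", sep="\t", index=False, float_format="%.10g"
    )
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(hist.counts, index=hist.labels, columns=hist.labels).to_csv(
        out / "histogram.tsv", sep="\t"
    )

    print("loss summary (% relative to the best cap pair):")
    print(summary.to_string(index=False))
    s = summary.set_index("channel")
    print(f"\nOrdering: full ear grid ({s.loc['ear_grid', 'mean']:.1f}%) < "
          f"vertical bipolar ({s.loc['vertical', 'mean']:.1f}%) < "
          f"horizontal bipolar ({s.loc['horizontal', 'mean']:.1f}%) — the "
          "exhaustive pair search over 190 bilateral pairs can only beat any "
          "fixed pair, and the vertical pair spans a larger distance than "
          "the horizontal one.")
    print(f"winning-pair histogram over the {hist.total} patches with "
          f"below-average loss written to {out / 'histogram.tsv'}")


if __name__ == "__main__":
    main()
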