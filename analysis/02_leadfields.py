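#!/usr/bin/env python
"""Compute the average-referenced surface-normal lead fields.

One column per cortex vertex (constrained orientation along the outward
normal, unit moment), for the 128-channel cap and the bilateral 20-channel
ear montage, using the multilayer-sphere series.  Written to
results/leadfields/.
"""

from pathlib import Path

import numpy as np

from earfield.cli import load_head
from earfield.forward import compute_leadfield
from earfield.io import write_leadfield

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    head = load_head(ROOT / "head")
    out = ROOT / "leadfields"
    out.mkdir(parents=True, exist_ok=True)
    for name, montage in (
        ("cap", head.cap),
        ("ear_bilateral", head.ear_montage),
    ):
        lf = compute_leadfield(montage, head.cortex, head.shell)
        write_leadfield(lf, out / f"{name}.tsv")
        # V per (A*m) is numerically nV per (nA*m)
        amp = np.abs(lf.matrix).max()
        print(f"{name}: {lf.n_channels} channels x {lf.n_columns} sources, "
              f"max |entry| {amp:.0f} nV per nA*m")
    print(f"lead fields written to {out}")


if __name__ == "__main__":
    main()
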