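"""Small packaged fixture datasets for tests and worked examples."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np

from .io import write_labeled_predictions
from .simulator import SCENARIO_NAMES, sample_labeled_predictions

__all__ = ["generate_fixtures", "WORKED_EXAMPLE_CELLS"]

#: the two classic fixed-rate worked examples: (tp, fn, fp, tn) at N=100,
#: prevalence 0.5, from TPR=TNR=0.8 and TPR=0.7/TNR=0.9 — both give TSS 0.6
WORKED_EXAMPLE_CELLS = {
    "tpr08_tnr08": (40, 10, 10, 40),
    "tpr07_tnr09": (35, 15, 5, 45),
}

_FIXTURE_N = 100
_FIXTURE_PREVALENCE = 0.5


def generate_fixtures(out_dir: Union[str, Path], seed: int = 0) -> list[Path]:
    """Write the fixture set: one labeled-prediction file per scenario
    (N=100, prevalence 0.5) plus the worked-example confusion matrices.

    Deterministic: a fixed seed reproduces the files byte for byte.
    Returns the list of paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i, name in enumerate(SCENARIO_NAMES):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(np.uint32(i),))
        data = sample_labeled_predictions(
            name, _FIXTURE_N, _FIXTURE_PREVALENCE,
            np.random.Generator(np.random.PCG64(ss)),
        )
        path = out_dir / f"predictions_{name}.csv"
        write_labeled_predictions(data, path)
        # record the root seed in place of the unprintable stream object
        text = path.read_text().replace("label,probability",
                                        f"# seed: {seed}\nlabel,probability", 1)
        path.write_text(text)
        written.append(path)
    for tag, (tp, fn, fp, tn) in WORKED_EXAMPLE_CELLS.items():
        path = out_dir / f"confusion_{tag}.csv"
        with open(path, "w") as fh:
            fh.write("# fixed-rate worked example, N=100, prevalence 0.5\n")
            fh.write("tp,fn,fp,tn\n")
            fh.write(f"{tp},{fn},{fp},{tn}\n")
        written.append(path)
    return written
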