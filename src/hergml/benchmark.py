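"""Published benchmark confusion matrices for hERG blocker classifiers.

The packaged CSV holds the validation-set (VS) and temporal external-set
(ES) confusion counts reported in the literature for single and consensus
hERG-blockade classifiers at both potency thresholds, together with the
metric values as printed.  Recomputing BA/SE/SP/MCC from the raw counts
with this package's evaluation module and comparing against the printed
values is a fast, deterministic verification of the metric arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from hergml.evaluation import ConfusionCounts, cooper_stats, mcc, round_half_up


def load_benchmark() -> pd.DataFrame:
    """The packaged benchmark table (one row per model/dataset)."""
    with resources.files("hergml.data").joinpath("benchmark_confusion.csv").open() as fh:
        return pd.read_csv(fh)


def recompute_metrics(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute SE/SP/BA/MCC from the stored counts.

    Adds columns ``SE``, ``SP``, ``BA``, ``MCC`` (unrounded) and
    ``*_matches_reported`` booleans comparing the half-up 2-decimal rounding
    of each recomputed value with the printed one.
    """
    if df is None:
        df = load_benchmark()
    out = df.copy()
    ses, sps, bas, mccs = [], [], [], []
    for _, row in df.iterrows():
        c = ConfusionCounts(TP=int(row.TP), FP=int(row.FP), TN=int(row.TN), FN=int(row.FN))
        se, sp, ba = cooper_stats(c)
        ses.append(se)
        sps.append(sp)
        bas.append(ba)
        mccs.append(mcc(c))
    out["SE"], out["SP"], out["BA"], out["MCC"] = ses, sps, bas, mccs
    for m in ("SE", "SP", "BA", "MCC"):
        out[f"{m}_matches_reported"] = [
            abs(round_half_up(v, 2) - r) < 1e-9
            for v, r in zip(out[m], out[f"reported_{m}"])
        ]
    return out
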