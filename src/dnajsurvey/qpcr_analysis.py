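"""Relative qPCR quantification by the 2^-ddCt method.

Replicate Ct values are averaged per (gene, condition); dCt is the target
minus the reference gene (here typically UBI) within each condition, ddCt
is treatment minus control, and fold change is 2^-ddCt. Amplification
efficiency is fixed at 2 (no efficiency correction), matching the method.
Up/down thresholds are conventions (2-fold / 0.5-fold by default), with a
separate strong-response flag at 3-fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene", "condition", "replicate", "ct")
CONDITIONS = ("control", "treatment")


@dataclass(frozen=True)
class FoldChangeCall:
    gene: str
    fold: float
    replicate_sd: float
    call: str = ""  # up | down | unchanged (set by call_response)
    strong_up: bool = False

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")


def read_qpcr_tsv(path: str | Path) -> pd.DataFrame:
    """Long-format Ct table; accepts plain or '#'-prefixed header lines."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#"):
            cols = first[1:].split("\t")
            df = pd.read_csv(fh, sep="\t", header=None, names=cols)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if not df.ct.between(0, 45, inclusive="neither").all():
        raise ValueError("Ct values must lie in (0, 45)")
    return df


def ddct_fold(
    table: pd.DataFrame,
    gene: str,
    reference_gene: str,
    per_replicate: bool = False,
) -> FoldChangeCall:
    """Fold change of one gene relative to the reference under treatment.

    Default mode averages replicate Ct per (gene, condition) before taking
    differences; ``per_replicate`` pairs replicates by index, computes a
    ddCt per replicate and averages those. The replicate SD is propagated
    from the target gene's Ct spread in the two conditions
    (sqrt(sd_control^2 + sd_treatment^2), in cycles).
    """
    if gene == reference_gene:
        logger.warning("target equals reference gene %s; fold is 1 by definition", gene)
        return FoldChangeCall(gene=gene, fold=1.0, replicate_sd=0.0)

    def cts(g: str, cond: str) -> np.ndarray:
        vals = table.loc[(table.gene == g) & (table.condition == cond), "ct"].to_numpy()
        if len(vals) == 0:
            raise ValueError(f"no Ct values for gene {g!r} in condition {cond!r}")
        return vals

    t_ctrl, t_trt = cts(gene, "control"), cts(gene, "treatment")
    r_ctrl, r_trt = cts(reference_gene, "control"), cts(reference_gene, "treatment")
    if per_replicate and len(t_ctrl) == len(t_trt) == len(r_ctrl) == len(r_trt):
        ddct = float(np.mean((t_trt - r_trt) - (t_ctrl - r_ctrl)))
    else:
        dct_ctrl = t_ctrl.mean() - r_ctrl.mean()
        dct_trt = t_trt.mean() - r_trt.mean()
        ddct = float(dct_trt - dct_ctrl)
    sd = float(math.sqrt(np.var(t_ctrl, ddof=1 if len(t_ctrl) > 1 else 0)
                         + np.var(t_trt, ddof=1 if len(t_trt) > 1 else 0)))
    return FoldChangeCall(gene=gene, fold=float(2.0 ** (-ddct)), replicate_sd=sd)


def all_fold_changes(
    table: pd.DataFrame, reference_gene: str, per_replicate: bool = False
) -> list[FoldChangeCall]:
    genes = [g for g in table.gene.unique() if g != reference_gene]
    return [ddct_fold(table, g, reference_gene, per_replicate) for g in genes]


def call_response(
    folds: Sequence[FoldChangeCall],
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
    strong_threshold: float = 3.0,
) -> list[FoldChangeCall]:
    """Label each fold change up/down/unchanged, flagging strong induction."""
    out = []
    for f in folds:
        if f.fold >= up_threshold:
            call = "up"
        elif f.fold <= down_threshold:
            call = "down"
        else:
            call = "unchanged"
        out.append(
            FoldChangeCall(
                gene=f.gene, fold=f.fold, replicate_sd=f.replicate_sd,
                call=call, strong_up=f.fold >= strong_threshold,
            )
        )
    return out


def calls_to_table(calls: Sequence[FoldChangeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": c.gene, "fold": c.fold, "sd": c.replicate_sd,
             "call": c.call, "strong_up": c.strong_up}
            for c in calls
        ],
        columns=["gene", "fold", "sd", "call", "strong_up"],
    )
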