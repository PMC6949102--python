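"""Differential lncRNA expression: per-instance fold changes, DEL calls,
and per-drug merging into signed drug-lncRNA associations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DrugLncRNAAssociation:
    """A signed SMLN edge: a drug and a lncRNA it differentially regulates.

    ``sign`` is "up" or "down" and is consistent with the sign of
    ``mean_log2fc``; ``n_supporting_instances`` counts the instances whose
    fold change exceeded the threshold with the winning sign.
    """

    drug_id: str
    lncrna_id: str
    sign: str
    mean_log2fc: float
    n_supporting_instances: int

    def __post_init__(self) -> None:
        if self.sign not in ("up", "down"):
            raise ValueError(f"sign must be 'up' or 'down', got {self.sign!r}")
        if self.n_supporting_instances < 1:
            raise ValueError("n_supporting_instances must be >= 1")


def compute_log2fc(
    treatment: np.ndarray | pd.Series,
    control: np.ndarray | pd.Series,
    values_are_log2: bool = True,
):
    """Per-feature log2 fold change of a treatment over its paired control.

    With log2-scale inputs this is an elementwise subtraction; with
    linear-scale inputs, log2(t / c) (all values must be positive).
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.shape != c.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {c.shape}")
    if values_are_log2:
        fc = t - c
    else:
        if np.any(t <= 0) or np.any(c <= 0):
            raise ValueError("linear-scale expression values must be positive")
        fc = np.log2(t / c)
    if isinstance(treatment, pd.Series):
        return pd.Series(fc, index=treatment.index)
    return fc


def call_dels(fc: pd.Series, threshold: float = 1.0) -> set[tuple[str, str]]:
    """Call differentially expressed lncRNAs from one instance's fold changes.

    A lncRNA is a DEL iff |log2FC| strictly exceeds ``threshold``; the sign
    is "up" for positive and "down" for negative fold change.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = set()
    for lnc, v in fc.items():
        if abs(v) > threshold:
            out.add((lnc, "up" if v > 0 else "down"))
    return out


def merge_per_drug(
    instance_dels: Mapping[str, set[tuple[str, str]]],
    instance_drug: Mapping[str, str],
    fc_records: Mapping[tuple[str, str], float],
) -> list[DrugLncRNAAssociation]:
    """Merge instance-level DEL calls into per-drug signed associations.

    The association set per drug is the union of its instances' DELs.  For
    each (drug, lncRNA) the sign is the majority sign over above-threshold
    instances; ties go to the sign with larger mean |log2FC|, then to "up".
    ``mean_log2fc`` and ``n_supporting_instances`` are computed over the
    instances supporting the winning sign only, keeping the sign and the
    mean consistent.

    ``fc_records`` maps (instance_id, lncrna_id) to the instance log2FC.
    """
    per_pair: dict[tuple[str, str], dict[str, list[float]]] = {}
    for inst, dels in instance_dels.items():
        if inst not in instance_drug:
            raise KeyError(f"instance {inst!r} does not map to a drug")
        drug = instance_drug[inst]
        for lnc, sign in dels:
            fc = fc_records[(inst, lnc)]
            per_pair.setdefault((drug, lnc), {"up": [], "down": []})[sign].append(fc)

    associations = []
    for (drug, lnc), by_sign in sorted(per_pair.items()):
        n_up, n_down = len(by_sign["up"]), len(by_sign["down"])
        if n_up > n_down:
            win = "up"
        elif n_down > n_up:
            win = "down"
        else:
            mean_up = float(np.mean(np.abs(by_sign["up"])))
            mean_down = float(np.mean(np.abs(by_sign["down"])))
            win = "up" if mean_up >= mean_down else "down"
        support = by_sign[win]
        associations.append(
            DrugLncRNAAssociation(
                drug_id=drug,
                lncrna_id=lnc,
                sign=win,
                mean_log2fc=float(np.mean(support)),
                n_supporting_instances=len(support),
            )
        )
    return associations


def associations_from_instances(
    expr: pd.DataFrame,
    manifest: pd.DataFrame,
    threshold: float = 1.0,
    values_are_log2: bool = True,
) -> list[DrugLncRNAAssociation]:
    """End-to-end DEL pipeline: fold changes per instance, DEL calls, merge.

    ``expr`` is a feature x sample matrix; ``manifest`` has columns
    instance_id, drug_id, treatment_sample, control_sample.
    """
    required = {"instance_id", "drug_id", "treatment_sample", "control_sample"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    instance_dels: dict[str, set[tuple[str, str]]] = {}
    instance_drug: dict[str, str] = {}
    fc_records: dict[tuple[str, str], float] = {}
    for row in manifest.itertuples(index=False):
        fc = compute_log2fc(
            expr[row.treatment_sample], expr[row.control_sample], values_are_log2
        )
        instance_dels[row.instance_id] = call_dels(fc, threshold)
        instance_drug[row.instance_id] = row.drug_id
        for lnc, v in fc.items():
            fc_records[(row.instance_id, lnc)] = float(v)
    return merge_per_drug(instance_dels, instance_drug, fc_records)
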