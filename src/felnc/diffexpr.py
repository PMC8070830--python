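"""Nonparametric noise-dominance differential expression and expression classes.

The DE probability follows the replicate-based signal-vs-noise dominance
idea: the per-transcript signal is (|M|, D), with M the pseudocounted log2
fold change of deficient over sufficient condition means and D the absolute
difference of those means; the noise distribution pools (M, D) values from
every unordered within-condition replicate pair over all transcripts. The
probability is the fraction of noise points strictly dominated by the
signal. DE calls then apply the |log2FC| > 1, FPKM > 2, probability > 0.8
filter, and calls from the two tissues combine into expression classes I-V
(I root-down, II root-up, III shoot-down, IV shoot-up, V up in both).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ValidationError

__all__ = [
    "DEThresholds",
    "noiseq_probability",
    "call_de",
    "assign_expression_class",
    "classify_expression",
    "compare_de_sets",
    "de_summary",
]

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DEThresholds:
    """DE filter constants; defaults are the study's published thresholds."""

    min_abs_m: float = 1.0  # |log2 fold change| must strictly exceed this
    min_fpkm: float = 2.0  # max(condition means) must strictly exceed this
    min_probability: float = 0.8  # strictly exceeded

    def validate(self) -> None:
        if not (0.0 <= self.min_probability <= 1.0):
            raise ValidationError("probability threshold must lie in [0, 1]")
        if self.min_fpkm < 0 or self.min_abs_m < 0:
            raise ValidationError("thresholds must be non-negative")


def noiseq_probability(
    fpkm: ExpressionMatrix, tissue: str, k: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-transcript (M, D, probability) for deficient vs sufficient iron.

    Requires >= 2 replicates per iron condition within the tissue. The
    pseudocount ``k`` enters M only. Probability counts strict dominance:
    |M_noise| < |M_t| and D_noise < D_t over the pooled noise set.
    """
    if fpkm.unit != "FPKM":
        raise ValidationError("noiseq_probability expects an FPKM matrix")
    if tissue not in ("shoot", "root"):
        raise ValidationError(f"unknown tissue {tissue!r}")
    suf = [s for s in fpkm.samples if s.tissue == tissue and s.iron == "sufficient"]
    def_ = [s for s in fpkm.samples if s.tissue == tissue and s.iron == "deficient"]
    if len(suf) < 2 or len(def_) < 2:
        raise ValidationError(
            f"tissue {tissue!r}: need >= 2 replicates per iron condition"
        )
    x_suf = fpkm.values[[s.sample_id for s in suf]].to_numpy(dtype=float)
    x_def = fpkm.values[[s.sample_id for s in def_]].to_numpy(dtype=float)
    mu_suf = x_suf.mean(axis=1)
    mu_def = x_def.mean(axis=1)
    m = np.log2((mu_def + k) / (mu_suf + k))
    d = np.abs(mu_def - mu_suf)

    noise_m: list[np.ndarray] = []
    noise_d: list[np.ndarray] = []
    for x in (x_suf, x_def):
        for i, j in combinations(range(x.shape[1]), 2):
            noise_m.append(np.log2((x[:, i] + k) / (x[:, j] + k)))
            noise_d.append(np.abs(x[:, i] - x[:, j]))
    nm = np.abs(np.concatenate(noise_m))
    nd = np.concatenate(noise_d)
    if nm.size == 0:
        raise ValidationError("empty noise set")

    am = np.abs(m)
    prob = np.empty(len(am))
    chunk = max(1, int(2e7 // max(nm.size, 1)))
    for lo in range(0, len(am), chunk):
        hi = min(lo + chunk, len(am))
        dominated = (nm[None, :] < am[lo:hi, None]) & (nd[None, :] < d[lo:hi, None])
        prob[lo:hi] = dominated.sum(axis=1) / nm.size

    detected = (x_suf.sum(axis=1) + x_def.sum(axis=1)) > 0
    return pd.DataFrame(
        {
            "tissue": tissue,
            "mean_suf": mu_suf,
            "mean_def": mu_def,
            "M": m,
            "D": d,
            "probability": prob,
            "fpkm_max": np.maximum(mu_suf, mu_def),
            "detected": detected,
        },
        index=fpkm.values.index.rename("transcript_id"),
    )


def call_de(stats: pd.DataFrame, thresholds: DEThresholds = DEThresholds()) -> pd.DataFrame:
    """Add a ``status`` column: up / down / ns / not_detected.

    up requires M > 1, probability > 0.8 and fpkm_max > 2 (strict, with the
    configured constants); down is symmetric with M < -1. Transcripts with
    all-zero abundance in the tissue are reported as not_detected.
    """
    thresholds.validate()
    out = stats.copy()
    passes = (out["probability"] > thresholds.min_probability) & (
        out["fpkm_max"] > thresholds.min_fpkm
    )
    status = np.where(
        passes & (out["M"] > thresholds.min_abs_m),
        "up",
        np.where(passes & (out["M"] < -thresholds.min_abs_m), "down", "ns"),
    )
    status = np.where(out["detected"], status, "not_detected")
    out["status"] = status
    return out


_CLASS_MAP = {
    ("ns", "down"): "I",
    ("ns", "up"): "II",
    ("down", "ns"): "III",
    ("up", "ns"): "IV",
    ("up", "up"): "V",
}


def assign_expression_class(shoot_status: str, root_status: str) -> str:
    """Expression class from the (shoot, root) DE status pair.

    (ns, down) -> I; (ns, up) -> II; (down, ns) -> III; (up, ns) -> IV;
    (up, up) -> V; remaining combinations with at least one call -> other;
    (ns, ns) -> none. not_detected is treated as ns for classing.
    """
    valid = {"up", "down", "ns", "not_detected"}
    if shoot_status not in valid or root_status not in valid:
        raise ValidationError(
            f"unknown status pair ({shoot_status!r}, {root_status!r})"
        )
    s = "ns" if shoot_status == "not_detected" else shoot_status
    r = "ns" if root_status == "not_detected" else root_status
    if (s, r) == ("ns", "ns"):
        return "none"
    return _CLASS_MAP.get((s, r), "other")


def classify_expression(shoot: pd.DataFrame, root: pd.DataFrame) -> pd.DataFrame:
    """Class I-V table over transcripts DE in at least one tissue."""
    ids = shoot.index.union(root.index)
    s_status = shoot["status"].reindex(ids, fill_value="ns")
    r_status = root["status"].reindex(ids, fill_value="ns")
    classes = [
        assign_expression_class(s, r) for s, r in zip(s_status, r_status)
    ]
    df = pd.DataFrame(
        {"shoot_status": s_status, "root_status": r_status, "class": classes},
        index=ids.rename("transcript_id"),
    )
    return df[df["class"] != "none"]


@dataclass
class DESetComparison:
    shared: set[tuple[str, str]]
    a_only: set[tuple[str, str]]
    b_only: set[tuple[str, str]]
    antagonistic: set[tuple[str, str]]

    @property
    def venn_counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
            "antagonistic": len(self.antagonistic),
        }


def compare_de_sets(a: pd.DataFrame, b: pd.DataFrame) -> DESetComparison:
    """Compare two DE tables keyed by (transcript_id, tissue).

    Significant calls are status in {up, down}. ``antagonistic`` holds keys
    called up in one table and down in the other — the signature of
    transcripts whose iron response flips between the two contrasts.
    """

    def _sig(df: pd.DataFrame) -> dict[tuple[str, str], str]:
        sig = df[df["status"].isin(["up", "down"])]
        return {
            (tid, tis): st
            for tid, tis, st in zip(sig.index, sig["tissue"], sig["status"])
        }

    sa, sb = _sig(a), _sig(b)
    keys_a, keys_b = set(sa), set(sb)
    shared = keys_a & keys_b
    antagonistic = {k for k in shared if sa[k] != sb[k]}
    return DESetComparison(shared, keys_a - keys_b, keys_b - keys_a, antagonistic)


def de_summary(tables: dict[str, pd.DataFrame], classes: pd.DataFrame) -> dict:
    """Counts of up/down per tissue plus class sizes, JSON-serializable."""
    out: dict = {"per_tissue": {}, "class_sizes": {}}
    for tissue, df in tables.items():
        out["per_tissue"][tissue] = {
            "up": int((df["status"] == "up").sum()),
            "down": int((df["status"] == "down").sum()),
        }
    for cls, n in classes["class"].value_counts().items():
        out["class_sizes"][str(cls)] = int(n)
    return out
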