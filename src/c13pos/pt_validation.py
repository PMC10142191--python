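"""Accuracy evaluation against binomial ¹³C-PT isotopic standards.

¹³C-PT standards carry equal proportions of every positional isotopomer, so
every n-carbon fragment has the Binomial(n, 1/2) CID — Pascal's triangle row
n after rescaling by 2^n — and every position a mean enrichment of exactly
0.5.  Measured CIDs and positional calculations are compared with those
expectations through 95% confidence intervals over replicates (mean ±
1.96·SD/√k, normal approximation); a value is flagged biased when the
expectation falls outside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragment_library import load_fragment_table, registry_index
from .positional_solver import published_combinations

__all__ = [
    "ExpectedCID",
    "BiasVerdict",
    "expected_binomial_cid",
    "ci95",
    "flag_bias",
    "validation_report",
]


@dataclass(frozen=True)
class ExpectedCID:
    """Expected binomial CID of an n-carbon PT-standard fragment."""

    n: int
    fractions: tuple[float, ...]
    pascal: tuple[int, ...]

    @property
    def mean_enrichment(self) -> float:
        return 0.5


def expected_binomial_cid(n: int) -> ExpectedCID:
    """Binomial(n, 1/2) fractions and their Pascal-triangle rescaling (x 2^n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pascal = tuple(comb(n, i) for i in range(n + 1))
    return ExpectedCID(n=n,
                       fractions=tuple(c / 2 ** n for c in pascal),
                       pascal=pascal)


def ci95(values: Sequence[float]) -> tuple[float, float]:
    """95% confidence interval mean ± 1.96 · SD/√k (sample SD, k−1 denominator).

    The 1.96 normal-approximation factor is used as published rather than a
    t-quantile, so the arithmetic matches the original evaluation exactly.
    """
    values = np.asarray(values, dtype=float)
    k = len(values)
    if k < 2:
        raise ValueError("need at least 2 replicate values for a CI")
    m = float(values.mean())
    half = 1.96 * float(values.std(ddof=1)) / sqrt(k)
    return (m - half, m + half)


@dataclass(frozen=True)
class BiasVerdict:
    """Measured-vs-expected comparison for one quantity."""

    quantity_id: str
    mean: float
    sd: float
    k: int
    expected: float
    ci_low: float
    ci_high: float
    biased: bool


def flag_bias(measured: Sequence[float], expected: float,
              quantity_id: str = "") -> BiasVerdict:
    """Flag a quantity as biased when its expectation lies outside the 95% CI.

    A tiny absolute guard band (1e-9) keeps noiseless data — where both the
    deviation and the CI width are at machine precision — from being flagged
    on floating-point round-off.
    """
    lo, hi = ci95(measured)
    arr = np.asarray(measured, dtype=float)
    tol = 1e-9
    return BiasVerdict(
        quantity_id=quantity_id,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        k=len(arr),
        expected=expected,
        ci_low=lo,
        ci_high=hi,
        biased=not (lo - tol <= expected <= hi + tol),
    )


def validation_report(fragment_cids: Mapping[str, Sequence[Sequence[float]]],
                      positional_values: Mapping[str, Sequence[float]] | None = None
                      ) -> pd.DataFrame:
    """Expected-vs-measured verdict table for a PT-standard dataset.

    ``fragment_cids`` maps fragment_id -> per-replicate corrected CID vectors;
    ``positional_values`` maps combination name -> per-replicate positional
    values.  The table carries one row per fragment isotopologue (expected
    binomial fraction), one per fragment mean enrichment (expected 0.5) and
    one per positional combination (expected 0.5), each with its CI and bias
    flag, mirroring the figures of the standard-based evaluation.
    """
    idx = registry_index(load_fragment_table())
    records = []
    for frag_id, reps in sorted(fragment_cids.items()):
        frag = idx[frag_id]
        n = frag.n_backbone
        exp = expected_binomial_cid(n)
        reps = [np.asarray(r, dtype=float) for r in reps]
        for i in range(n + 1):
            v = flag_bias([r[i] for r in reps], exp.fractions[i],
                          quantity_id=f"{frag_id}_M{i}")
            records.append(_row(v, kind="isotopologue_fraction",
                                metabolite=frag.metabolite, fragment=frag_id))
        enr = [float(np.dot(np.arange(n + 1), r) / n) for r in reps]
        v = flag_bias(enr, 0.5, quantity_id=f"{frag_id}_mean_enrichment")
        records.append(_row(v, kind="mean_enrichment",
                            metabolite=frag.metabolite, fragment=frag_id))
    if positional_values:
        combos = {c.name: c for c in published_combinations()}
        for name, reps in sorted(positional_values.items()):
            combo = combos.get(name)
            v = flag_bias(list(reps), 0.5, quantity_id=name)
            records.append(_row(
                v, kind="positional_enrichment",
                metabolite=combo.metabolite if combo else "",
                fragment=name))
    return pd.DataFrame.from_records(records)


def _row(v: BiasVerdict, kind: str, metabolite: str, fragment: str) -> dict:
    return {
        "metabolite": metabolite,
        "id": v.quantity_id,
        "kind": kind,
        "fragment_or_combination": fragment,
        "mean": v.mean,
        "sd": v.sd,
        "k": v.k,
        "expected": v.expected,
        "ci_low": v.ci_low,
        "ci_high": v.ci_high,
        "biased": v.biased,
    }
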