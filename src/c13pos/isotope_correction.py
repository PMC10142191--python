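"""Correction of raw isotopic-cluster areas for naturally occurring isotopes.

A measured GC-EI-MS isotopic cluster of a fragment mixes the carbon labeling
signal of interest with mass shifts caused by natural isotopes of every atom
in the fragment (H, N, O, Si and the derivatization carbons).  This module
builds, per fragment, a correction matrix whose column *j* is the predicted
measured cluster of the pure *j*-labeled carbon isotopologue, and inverts the
mixing by non-negative least squares.  Two optional backbone terms reproduce
tracer experiments: natural ¹³C abundance on unlabeled backbone carbons
(mass surpluses) and tracer isotopic purity on labeled ones (mass deficits),
so that natural-abundance material corrects to 0% enrichment and fully
labeled material at the tracer's purity corrects to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

from .fragment_library import ElementalFormula, FragmentDefinition

__all__ = [
    "IsotopeTable",
    "CorrectionOptions",
    "CorrectionMatrix",
    "CIDVector",
    "shift_distribution",
    "build_correction_matrix",
    "correct_areas",
    "mean_enrichment",
]

#: Relative abundance of the mass-shift isotopes of each element
#: (shift 0 = lightest isotope).  Values sum to 1 per element.
_DEFAULT_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.989, 0.011),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "Si": (0.9223, 0.0467, 0.0310),
}


@dataclass(frozen=True)
class IsotopeTable:
    """Natural-isotope mass-shift distributions per element.

    ``c13_abundance`` overrides the carbon entry so the 1.1% natural ¹³C
    level used throughout can be changed in one place.
    """

    abundances: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_ABUNDANCES))
    c13_abundance: float = 0.011

    def __post_init__(self):
        ab = dict(self.abundances)
        ab["C"] = (1.0 - self.c13_abundance, self.c13_abundance)
        object.__setattr__(self, "abundances", ab)
        for el, vals in ab.items():
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"abundances for {el} do not sum to 1: {vals}")
            if vals[0] <= 0:
                raise ValueError(f"element {el} must have a shift-0 isotope")

    def atom_distribution(self, element: str) -> np.ndarray:
        return np.asarray(self.abundances[element], dtype=float)


@dataclass(frozen=True)
class CorrectionOptions:
    """Which corrections to apply beyond non-backbone natural isotopes.

    The backbone natural-abundance term and the tracer-purity term describe
    the two faces of one tracer experiment, so they are switched together by
    ``correct_backbone``: off for isotopic standards with fully controlled
    ¹²C/¹³C patterns, on for tracer incorporation samples.
    """

    correct_backbone: bool = False
    tracer_purity: float = 0.99

    def __post_init__(self):
        if not (0.0 < self.tracer_purity <= 1.0):
            raise ValueError("tracer purity must be in (0, 1]")


def shift_distribution(f: ElementalFormula | dict[str, int],
                       exclude_backbone_c: int,
                       table: IsotopeTable | None = None,
                       window: int | None = None) -> np.ndarray:
    """Mass-shift distribution of a formula's natural isotopes.

    Convolves the per-atom isotope shift distributions of every atom except
    ``exclude_backbone_c`` carbon atoms (those carry the labeling signal and
    are handled separately).  Returns shifts 0..window, or the full
    untruncated distribution when ``window`` is None.
    """
    if table is None:
        table = IsotopeTable()
    if window is not None and window < 0:
        raise ValueError("window must be >= 0")
    counts = dict(f)
    n_c = counts.get("C", 0)
    if exclude_backbone_c > n_c:
        raise ValueError(
            f"cannot exclude {exclude_backbone_c} carbons from a formula with {n_c}")
    if exclude_backbone_c:
        counts["C"] = n_c - exclude_backbone_c
        if counts["C"] == 0:
            del counts["C"]
    dist = np.array([1.0])
    for el, n in counts.items():
        atom = table.atom_distribution(el)
        for _ in range(n):
            dist = np.convolve(dist, atom)
    if window is not None:
        out = np.zeros(window + 1)
        upto = min(len(dist), window + 1)
        out[:upto] = dist[:upto]
        return out
    return dist


@dataclass(frozen=True)
class CorrectionMatrix:
    """Per-fragment mixing matrix over the measured cluster window M0..Mn."""

    fragment_id: str
    matrix: np.ndarray          # shape (n+1, n+1); column j = isotopologue j
    options: CorrectionOptions

    @property
    def n_backbone(self) -> int:
        return self.matrix.shape[0] - 1


def isotopologue_pattern(frag: FragmentDefinition, j: int,
                         table: IsotopeTable | None = None,
                         opts: CorrectionOptions | None = None) -> np.ndarray:
    """Full (untruncated) measured-shift distribution of the pure j-labeled
    isotopologue of ``frag``.

    The total mass shift is the sum of three independent contributions:
    ¹³C among the j tracer-designated backbone carbons (all j when the purity
    correction is off, Binomial(j, purity) otherwise), ¹³C among the n−j
    remaining backbone carbons (none when backbone correction is off,
    Binomial(n−j, natural ¹³C) otherwise), and natural isotopes of every
    non-backbone atom.
    """
    if table is None:
        table = IsotopeTable()
    if opts is None:
        opts = CorrectionOptions()
    n = frag.n_backbone
    if not 0 <= j <= n:
        raise ValueError(f"isotopologue index {j} outside 0..{n}")
    non_backbone = shift_distribution(frag.formula, exclude_backbone_c=n, table=table)
    if opts.correct_backbone:
        labeled = binom.pmf(np.arange(j + 1), j, opts.tracer_purity)
        unlabeled = binom.pmf(np.arange(n - j + 1), n - j, table.c13_abundance)
    else:
        labeled = np.zeros(j + 1)
        labeled[j] = 1.0
        unlabeled = np.array([1.0])
    return np.convolve(np.convolve(labeled, unlabeled), non_backbone)


def build_correction_matrix(frag: FragmentDefinition,
                            table: IsotopeTable | None = None,
                            opts: CorrectionOptions | None = None
                            ) -> CorrectionMatrix:
    """Build the (n+1)x(n+1) correction matrix of a fragment.

    Column j is the isotopologue-j pattern truncated to the measured window
    M0..Mn; the same truncation is applied by the simulator, so noiseless
    round trips are exact.
    """
    opts = opts or CorrectionOptions()
    n = frag.n_backbone
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        full = isotopologue_pattern(frag, j, table=table, opts=opts)
        upto = min(len(full), n + 1)
        M[:upto, j] = full[:upto]
    return CorrectionMatrix(frag.fragment_id, M, opts)


@dataclass(frozen=True)
class CIDVector:
    """Fractional carbon isotopologue distribution M0..Mn of one fragment."""

    fractions: np.ndarray
    residual: float = 0.0

    def __post_init__(self):
        fr = np.asarray(self.fractions, dtype=float)
        if np.any(fr < -1e-12) or np.any(fr > 1 + 1e-12):
            raise ValueError("isotopologue fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("isotopologue fractions must sum to 1")
        object.__setattr__(self, "fractions", fr)

    @property
    def n(self) -> int:
        return len(self.fractions) - 1

    def mean_enrichment(self) -> float:
        return mean_enrichment(self.fractions, self.n)


def correct_areas(raw: np.ndarray, M: CorrectionMatrix,
                  residual_warn: float = 1e-3) -> CIDVector:
    """Recover the fractional CID from raw cluster areas.

    Solves ``raw ≈ M @ x`` with x >= 0 (non-negative least squares; plain
    inversion can produce negative fractions on noisy data), then normalizes
    x to sum 1.  The relative residual of the fit is recorded on the result.
    """
    raw = np.asarray(raw, dtype=float)
    n1 = M.matrix.shape[0]
    if raw.shape != (n1,):
        raise ValueError(
            f"raw cluster has length {raw.shape}, expected ({n1},) = M0..Mn")
    if np.any(raw < 0):
        raise ValueError("raw areas must be non-negative")
    total = raw.sum()
    if total == 0:
        raise ValueError("raw cluster is all zero")
    x, rnorm = nnls(M.matrix, raw / total)
    if x.sum() == 0:
        raise ValueError("correction produced an all-zero solution")
    return CIDVector(x / x.sum(), residual=float(rnorm))


def mean_enrichment(cid: np.ndarray, n: int) -> float:
    """Fractional mean ¹³C enrichment: sum(i * Mi) / n."""
    cid = np.asarray(cid, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.dot(np.arange(len(cid)), cid) / n)
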