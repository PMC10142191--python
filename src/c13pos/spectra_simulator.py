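"""Synthetic GC-EI-MS area tables with known ground-truth labeling.

The forward model mirrors the correction exactly: a fragment's measured
cluster is the mixture of its isotopologue patterns (natural isotopes of
non-backbone atoms, plus — in tracer mode — tracer purity and natural ¹³C on
the backbone), weighted by the carbon isotopologue distribution implied by
the ground-truth positional labeling.  On top of that clean signal the
simulator can add co-eluting contaminant ions and multiplicative log-normal
noise.  Three dataset builders emulate the study designs the method is
evaluated on: binomial ¹³C-PT standards (every position labeled independently
with probability 0.5), U-¹³C-pyruvate incorporation kinetics under light and
dark conditions, and contaminant-injection experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fragment_library import (
    METABOLITE_CARBONS,
    FragmentDefinition,
    fragments_for,
    load_fragment_table,
    parse_formula,
)
from .isotope_correction import (
    CorrectionOptions,
    IsotopeTable,
    isotopologue_pattern,
    shift_distribution,
)

__all__ = [
    "LabelState",
    "ContaminantSpec",
    "SimulatedSample",
    "fragment_cid_from_positions",
    "simulate_fragment_areas",
    "simulate_pt_standard_dataset",
    "simulate_labeling_kinetics",
    "default_kinetics_scenario",
]


@dataclass(frozen=True)
class LabelState:
    """Ground-truth positional ¹³C labeling of one metabolite.

    Either ``position_probs`` (independent per-position labeling
    probabilities, length = backbone carbons) or ``isotopomer_probs`` (an
    explicit distribution over all 2^N positional isotopomers, keyed by
    binary tuples) is given.
    """

    metabolite: str
    position_probs: tuple[float, ...] | None = None
    isotopomer_probs: Mapping[tuple[int, ...], float] | None = None

    def __post_init__(self):
        n = METABOLITE_CARBONS[self.metabolite]
        if (self.position_probs is None) == (self.isotopomer_probs is None):
            raise ValueError("give exactly one of position_probs / isotopomer_probs")
        if self.position_probs is not None:
            p = tuple(float(x) for x in self.position_probs)
            if len(p) != n:
                raise ValueError(f"{self.metabolite} needs {n} position probabilities")
            if any(not 0 <= x <= 1 for x in p):
                raise ValueError("labeling probabilities must lie in [0, 1]")
            object.__setattr__(self, "position_probs", p)
        else:
            probs = dict(self.isotopomer_probs)
            if any(len(k) != n for k in probs):
                raise ValueError(f"isotopomer keys must have length {n}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("isotopomer distribution must sum to 1")
            object.__setattr__(self, "isotopomer_probs", probs)

    @property
    def n_carbons(self) -> int:
        return METABOLITE_CARBONS[self.metabolite]


def fragment_cid_from_positions(state: LabelState,
                                frag: FragmentDefinition) -> np.ndarray:
    """CID of a fragment implied by the ground-truth labeling.

    The CID is the distribution of the number of labeled carbons within the
    fragment's backbone subset: a Poisson-binomial (convolution of per-position
    Bernoullis) for independent positions, or a marginalization of the
    explicit isotopomer distribution.
    """
    if frag.metabolite != state.metabolite:
        raise ValueError(
            f"fragment {frag.fragment_id} does not match state for {state.metabolite}")
    k = frag.n_backbone
    if state.position_probs is not None:
        cid = np.array([1.0])
        for p in frag.backbone_positions:
            prob = state.position_probs[p - 1]
            cid = np.convolve(cid, [1.0 - prob, prob])
        return cid
    cid = np.zeros(k + 1)
    for pattern, prob in state.isotopomer_probs.items():
        labeled = sum(pattern[p - 1] for p in frag.backbone_positions)
        cid[labeled] += prob
    return cid


@dataclass(frozen=True)
class ContaminantSpec:
    """A co-eluting ion overlapping a fragment's isotopic cluster.

    ``mz_offset`` places the contaminant's own M0 relative to the fragment's
    M0 (may be negative); ``relative_intensity`` scales its M0 area as a
    fraction of the fragment's total area; ``formula`` (optional) spreads the
    contaminant over its own natural isotope pattern.
    """

    target_fragment: str
    mz_offset: int
    relative_intensity: float
    formula: str | None = None

    def __post_init__(self):
        if self.relative_intensity < 0:
            raise ValueError("contaminant intensity must be >= 0")

    def pattern(self, window_lo: int, window_hi: int,
                table: IsotopeTable | None = None) -> np.ndarray:
        """Contaminant area pattern over measured shifts window_lo..window_hi."""
        if self.formula is not None:
            base = shift_distribution(parse_formula(self.formula), 0, table)
        else:
            base = np.array([1.0])
        out = np.zeros(window_hi - window_lo + 1)
        for i, a in enumerate(base):
            m = self.mz_offset + i
            if window_lo <= m <= window_hi:
                out[m - window_lo] += a
        return out * self.relative_intensity


def simulate_fragment_areas(frag: FragmentDefinition,
                            cid: np.ndarray,
                            table: IsotopeTable | None = None,
                            opts: CorrectionOptions | None = None,
                            contaminants: Sequence[ContaminantSpec] = (),
                            noise_cv: float = 0.0,
                            rng: np.random.Generator | int | None = None,
                            total_area: float = 1e6,
                            truncate: bool = True) -> np.ndarray:
    """Forward-simulate the measured isotopic cluster of one fragment.

    Returns the window M0..Mn (or the full untruncated cluster when
    ``truncate`` is False).  Before noise and truncation, the clean areas sum
    to ``total_area`` times (1 + total contaminant fractions).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    table = table or IsotopeTable()
    opts = opts or CorrectionOptions()
    cid = np.asarray(cid, dtype=float)
    n = frag.n_backbone
    if cid.shape != (n + 1,):
        raise ValueError(f"CID must have length {n + 1} for {frag.fragment_id}")

    parts = [cid[j] * isotopologue_pattern(frag, j, table=table, opts=opts)
             for j in range(n + 1)]
    full_len = max(len(p) for p in parts)
    clean = np.zeros(full_len)
    for p in parts:
        clean[:len(p)] += p
    clean *= total_area

    for c in contaminants:
        if c.target_fragment == frag.fragment_id:
            clean += total_area * c.pattern(0, full_len - 1, table)

    if truncate:
        out = np.zeros(n + 1)
        upto = min(full_len, n + 1)
        out[:upto] = clean[:upto]
    else:
        out = clean

    if noise_cv > 0:
        rng = np.random.default_rng(rng)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        out = out * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=out.shape)
    return out


@dataclass(frozen=True)
class SimulatedSample:
    """One synthetic sample: area rows plus the ground truth that made them."""

    sample_id: str
    condition: str
    time_point: float
    replicate: int
    rows: tuple[tuple[str, float], ...]        # (fragment Name, Area), M0..Mn order
    ground_truth: tuple[LabelState, ...]
    seed: int

    def areas_for(self, fragment_id: str) -> np.ndarray:
        vals = [a for name, a in self.rows if name == fragment_id]
        if not vals:
            raise KeyError(f"{fragment_id} not present in sample {self.sample_id}")
        return np.asarray(vals)


def _sample_rows(states: Sequence[LabelState], table, opts, contaminants,
                 noise_cv, rng, total_area,
                 registry: Sequence[FragmentDefinition]) -> list[tuple[str, float]]:
    rows = []
    for state in states:
        for frag in fragments_for(state.metabolite, registry):
            cid = fragment_cid_from_positions(state, frag)
            areas = simulate_fragment_areas(
                frag, cid, table=table, opts=opts, contaminants=contaminants,
                noise_cv=noise_cv, rng=rng, total_area=total_area)
            rows.extend((frag.fragment_id, float(a)) for a in areas)
    return rows


def simulate_pt_standard_dataset(metabolites: Sequence[str] | None = None,
                                 n_replicates: int = 4,
                                 noise_cv: float = 0.0,
                                 seed: int = 0,
                                 contaminants: Sequence[ContaminantSpec] = (),
                                 table: IsotopeTable | None = None,
                                 total_area: float = 1e6
                                 ) -> list[SimulatedSample]:
    """Simulate ¹³C-PT isotopic standards.

    Every backbone position of every metabolite is labeled independently with
    probability 0.5, so each n-carbon fragment has a Binomial(n, 0.5) CID and
    a mean enrichment of exactly 0.5.  The standards hold fully controlled
    ¹²C/¹³C patterns, so the forward model applies no backbone
    natural-abundance or purity term (matching the correction mode used for
    them).  Four replicates by default.
    """
    metabolites = list(metabolites) if metabolites else sorted(METABOLITE_CARBONS)
    registry = load_fragment_table()
    opts = CorrectionOptions(correct_backbone=False)
    states = [LabelState(m, position_probs=(0.5,) * METABOLITE_CARBONS[m])
              for m in metabolites]
    samples = []
    for r in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(rep_seed)
        rows = _sample_rows(states, table, opts, contaminants, noise_cv, rng,
                            total_area, registry)
        samples.append(SimulatedSample(
            sample_id=f"PT_rep{r + 1}", condition="PT", time_point=0.0,
            replicate=r + 1, rows=tuple(rows), ground_truth=tuple(states),
            seed=rep_seed))
    return samples


def default_kinetics_scenario() -> dict[tuple[str, float], list[LabelState]]:
    """Tracer-incorporation time course emulating the light/dark leaf-disc design.

    Encodes the qualitative biology the positional method resolves:

    - serine acquires label only at C2 and only in the light (photorespiratory
      serine made by GDC/SHMT from one unlabeled and one C2-labeled glycine);
    - glycine likewise labels at C2 in the light, C1 stays unlabeled;
    - glutamate C1 labeling rises in the dark at late time points (second turn
      of the TCA cycle) while light stays near zero; C2–C5 label in both;
    - malate C1 labels similarly in both conditions (PEPc in the light
      compensating TCA turnover in the dark); C4 mirrors C1 via fumarase;
    - alanine, the pyruvate proxy, labels uniformly in both conditions;
    - every metabolite starts unlabeled at t = 0.

    Returns {(condition, time_h): [LabelState, ...]}.
    """
    times = [0.0, 1.0, 2.0, 4.0, 6.0]
    ramp = {0.0: 0.0, 1.0: 0.04, 2.0: 0.08, 4.0: 0.14, 6.0: 0.18}
    scenario: dict[tuple[str, float], list[LabelState]] = {}
    for cond in ("light", "dark"):
        for t in times:
            e = ramp[t]
            light = cond == "light"
            ser_c2 = e if light else 0.0
            glu_c1 = 0.0 if light else (0.0 if t < 2 else 0.03 * (t / 6.0) * 2)
            glu_rest = 0.5 * e
            mal_c1 = 0.6 * e
            states = [
                LabelState("Serine", position_probs=(0.0, ser_c2, 0.0)),
                LabelState("Glycine", position_probs=(0.0, ser_c2)),
                LabelState("Glutamate",
                           position_probs=(glu_c1, glu_rest, glu_rest,
                                           glu_rest, glu_rest)),
                LabelState("Malate",
                           position_probs=(mal_c1, 0.3 * e, 0.3 * e, mal_c1)),
                LabelState("Alanine", position_probs=(e, e, e)),
                LabelState("Proline",
                           position_probs=(0.2 * e,) + (0.3 * e,) * 4),
            ]
            scenario[(cond, t)] = states
    return scenario


def simulate_labeling_kinetics(scenario: Mapping[tuple[str, float], Sequence[LabelState]]
                               | None = None,
                               n_replicates: int = 4,
                               noise_cv: float = 0.01,
                               seed: int = 0,
                               tracer_purity: float = 0.99,
                               contaminants: Sequence[ContaminantSpec] = (),
                               table: IsotopeTable | None = None,
                               total_area: float = 1e6
                               ) -> list[SimulatedSample]:
    """Simulate a tracer-incorporation experiment (condition x time x replicate).

    Tracer mode: unlabeled backbone carbons sit at natural ¹³C abundance and
    labeled ones at the tracer's isotopic purity, so the matching full
    correction recovers the ground-truth tracer-incorporation probabilities
    (0 at t = 0, despite natural abundance).
    """
    scenario = scenario if scenario is not None else default_kinetics_scenario()
    registry = load_fragment_table()
    opts = CorrectionOptions(correct_backbone=True, tracer_purity=tracer_purity)
    samples = []
    for i, ((cond, t), states) in enumerate(sorted(scenario.items())):
        for r in range(n_replicates):
            rep_seed = int(np.random.SeedSequence([seed, i, r])
                           .generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(rep_seed)
            rows = _sample_rows(states, table, opts, contaminants, noise_cv,
                                rng, total_area, registry)
            samples.append(SimulatedSample(
                sample_id=f"{cond}_t{t:g}_rep{r + 1}", condition=cond,
                time_point=t, replicate=r + 1, rows=tuple(rows),
                ground_truth=tuple(states), seed=rep_seed))
    return samples
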