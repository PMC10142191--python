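"""End-to-end batch workflow: Name/Area tables in, enrichment tables out.

Reads per-sample GC-MS area tables (two columns, ``Name`` and ``Area``, one
row per m/z of a fragment's isotopic cluster in M0..Mn order, fragment names
spelled exactly as in the registry), corrects every cluster, computes
fragment mean enrichments and positional combinations per sample, and
compares conditions per time point with a two-sided Wilcoxon–Mann–Whitney
test.  Everything is a pure function of inputs and configuration.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu, shapiro

from .fragment_library import FragmentDefinition, registry_index
from .isotope_correction import (
    CorrectionOptions,
    IsotopeTable,
    build_correction_matrix,
    correct_areas,
)
from .positional_solver import (
    CombinationSpec,
    published_combinations,
    validated_combinations,
)
from .spectra_simulator import SimulatedSample

logger = logging.getLogger("c13pos")

__all__ = [
    "AreaTable",
    "GroupComparison",
    "PipelineConfig",
    "read_area_table",
    "write_area_table",
    "area_table_from_sample",
    "run_pipeline",
    "compare_groups",
]


@dataclass(frozen=True)
class AreaTable:
    """Raw Name/Area records of one sample plus its metadata."""

    sample_id: str
    rows: tuple[tuple[str, float], ...]
    condition: str = ""
    time_point: float = float("nan")
    replicate: int = 0

    def clusters(self) -> dict[str, np.ndarray]:
        """Group rows into per-fragment clusters, preserving M0..Mn order."""
        out: dict[str, list[float]] = {}
        for name, area in self.rows:
            out.setdefault(name, []).append(area)
        return {k: np.asarray(v) for k, v in out.items()}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one correction/positional run.

    ``correct_backbone`` selects tracer mode (backbone natural abundance +
    tracer purity convolved into the correction) versus standards mode (only
    non-backbone natural isotopes).  ``combinations`` chooses which
    positional combinations to evaluate: "validated" or "published" (all).
    """

    correct_backbone: bool = False
    tracer_purity: float = 0.99
    c13_abundance: float = 0.011
    combinations: str = "validated"
    condition_a: str = "light"
    condition_b: str = "dark"
    normality_check: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    def correction_options(self) -> CorrectionOptions:
        return CorrectionOptions(correct_backbone=self.correct_backbone,
                                 tracer_purity=self.tracer_purity)

    def isotope_table(self) -> IsotopeTable:
        return IsotopeTable(c13_abundance=self.c13_abundance)

    def combination_specs(self) -> list[CombinationSpec]:
        if self.combinations == "validated":
            return validated_combinations()
        if self.combinations == "published":
            return published_combinations()
        raise ValueError(f"unknown combination set {self.combinations!r}")


def read_area_table(path: str | Path,
                    registry: Iterable[FragmentDefinition] | None = None,
                    **metadata) -> AreaTable:
    """Read and validate one per-sample Name/Area file (TSV or CSV).

    Fragment names must match registry keys exactly; an unknown name raises
    with the nearest registry spelling.  Each named cluster must have exactly
    n_backbone + 1 rows (M0..Mn).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("Name", "Area") if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    idx = registry_index(registry) if registry is not None else registry_index()
    rows = []
    for name, area in zip(df["Name"], df["Area"]):
        if name not in idx:
            close = difflib.get_close_matches(str(name), idx.keys(), n=1)
            hint = f"; closest registry key: {close[0]!r}" if close else ""
            raise ValueError(f"{path.name}: unknown fragment name {name!r}{hint}")
        a = float(area)
        if a < 0:
            raise ValueError(f"{path.name}: negative area for {name}")
        rows.append((str(name), a))
    table = AreaTable(sample_id=metadata.pop("sample_id", path.stem),
                      rows=tuple(rows), **metadata)
    for name, cluster in table.clusters().items():
        want = idx[name].n_backbone + 1
        if len(cluster) != want:
            raise ValueError(
                f"{path.name}: cluster {name} has {len(cluster)} rows, "
                f"expected {want} (M0..Mn)")
    return table


def write_area_table(table: AreaTable, path: str | Path) -> None:
    """Write a sample back out in the Name/Area dialect (TSV or CSV)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(table.rows, columns=["Name", "Area"])
    df.to_csv(path, sep=sep, index=False)


def area_table_from_sample(sample: SimulatedSample) -> AreaTable:
    """Adapt a simulated sample to the pipeline's input type."""
    return AreaTable(sample_id=sample.sample_id, rows=sample.rows,
                     condition=sample.condition, time_point=sample.time_point,
                     replicate=sample.replicate)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Wilcoxon–Mann–Whitney comparison of two replicate groups."""

    quantity_id: str
    condition_a: str
    condition_b: str
    time_point: float
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    exact: bool

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_groups(a: Sequence[float], b: Sequence[float],
                   quantity_id: str = "", condition_a: str = "a",
                   condition_b: str = "b",
                   time_point: float = float("nan")) -> GroupComparison:
    """Two-sided rank-sum test; exact for tie-free groups of ≤ 8 each.

    Beyond 8 per group, or with ties (handled by mid-ranks), the
    tie-corrected normal approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    exact = (len(a) <= 8 and len(b) <= 8 and not has_ties)
    res = mannwhitneyu(a, b, alternative="two-sided",
                       method="exact" if exact else "asymptotic")
    return GroupComparison(
        quantity_id=quantity_id, condition_a=condition_a,
        condition_b=condition_b, time_point=time_point,
        n_a=len(a), n_b=len(b), statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)), exact=exact)


def _correct_sample(table: AreaTable, config: PipelineConfig,
                    matrices: Mapping[str, object],
                    idx: Mapping[str, FragmentDefinition]) -> list[dict]:
    records = []
    for name, cluster in table.clusters().items():
        if cluster.sum() == 0:
            logger.warning("sample %s: dropping all-zero cluster %s",
                           table.sample_id, name)
            continue
        frag = idx[name]
        cid = correct_areas(cluster, matrices[name])
        for i, f in enumerate(cid.fractions):
            records.append({
                "sample": table.sample_id,
                "condition": table.condition,
                "time_point": table.time_point,
                "replicate": table.replicate,
                "metabolite": frag.metabolite,
                "fragment": name,
                "isotopologue": i,
                "isotopologue_fraction": float(f),
                "mean_enrichment": cid.mean_enrichment(),
                "residuum": cid.residual,
            })
    return records


def run_pipeline(samples: Sequence[AreaTable],
                 config: PipelineConfig | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Correct, combine and compare a batch of samples.

    Returns three long-format tables:

    - corrected: one row per sample x fragment x isotopologue, with
      ``isotopologue_fraction`` and ``mean_enrichment`` columns;
    - positional: one row per sample x combination;
    - comparisons: one row per quantity x time point comparing the two
      configured conditions (skipped when either group is absent).
    """
    config = config or PipelineConfig()
    idx = registry_index()
    table = config.isotope_table()
    opts = config.correction_options()
    matrices = {fid: build_correction_matrix(frag, table, opts)
                for fid, frag in idx.items()}

    corrected_records: list[dict] = []
    for s in samples:
        corrected_records.extend(_correct_sample(s, config, matrices, idx))
    corrected = pd.DataFrame.from_records(corrected_records)

    specs = config.combination_specs()
    positional_records = []
    enr = (corrected.drop_duplicates(["sample", "fragment"])
           .set_index(["sample", "fragment"])["mean_enrichment"])
    meta = {s.sample_id: s for s in samples}
    seen = set(enr.index.get_level_values(0)) if len(enr) else set()
    for s in samples:
        sample_enr = enr.loc[s.sample_id].to_dict() if s.sample_id in seen else {}
        for spec in specs:
            if any(f not in sample_enr for f, _ in spec.terms):
                continue
            value = spec.evaluate(sample_enr)
            positional_records.append({
                "sample": s.sample_id,
                "condition": s.condition,
                "time_point": s.time_point,
                "replicate": s.replicate,
                "metabolite": spec.metabolite,
                "position": spec.target_label,
                "method": spec.method,
                "combination": spec.name,
                "value": value,
                "out_of_range": not (0.0 <= value <= 1.0),
                "verdict": spec.verdict,
            })
    positional = pd.DataFrame.from_records(positional_records)

    comparisons = _compare_conditions(corrected, positional, config, meta)
    return corrected, positional, comparisons


def _compare_conditions(corrected: pd.DataFrame, positional: pd.DataFrame,
                        config: PipelineConfig,
                        meta: Mapping[str, AreaTable]) -> pd.DataFrame:
    records = []
    frames = []
    if len(corrected):
        f = corrected.drop_duplicates(["sample", "fragment"])[
            ["sample", "condition", "time_point", "fragment", "mean_enrichment"]]
        frames.append(f.rename(columns={"fragment": "quantity",
                                        "mean_enrichment": "value"}))
    if len(positional):
        frames.append(positional[["sample", "condition", "time_point",
                                  "combination", "value"]]
                      .rename(columns={"combination": "quantity"}))
    if not frames:
        return pd.DataFrame()
    longdf = pd.concat(frames, ignore_index=True)
    for (quantity, t), grp in longdf.groupby(["quantity", "time_point"]):
        va = grp.loc[grp["condition"] == config.condition_a, "value"].to_numpy()
        vb = grp.loc[grp["condition"] == config.condition_b, "value"].to_numpy()
        if len(va) < 3 or len(vb) < 3:
            continue
        if config.normality_check:
            for cond, vals in ((config.condition_a, va), (config.condition_b, vb)):
                if len(vals) >= 3 and len(np.unique(vals)) > 1:
                    p = shapiro(vals).pvalue
                    if p < 0.05:
                        logger.info("normality rejected (Shapiro p=%.3g) for "
                                    "%s / %s / t=%g", p, quantity, cond, t)
        cmp_ = compare_groups(va, vb, quantity_id=quantity,
                              condition_a=config.condition_a,
                              condition_b=config.condition_b, time_point=t)
        records.append({
            "quantity": quantity,
            "time_point": t,
            "condition_a": cmp_.condition_a,
            "condition_b": cmp_.condition_b,
            "n_a": cmp_.n_a,
            "n_b": cmp_.n_b,
            "statistic": cmp_.statistic,
            "p_value": cmp_.p_value,
            "exact": cmp_.exact,
            "significant": cmp_.significant,
        })
    return pd.DataFrame.from_records(records)
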