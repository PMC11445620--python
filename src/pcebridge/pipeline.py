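"""End-to-end orchestration: configuration, the decomposition report and
the recomposition/coverage services the CLI exposes.

The decomposition pipeline runs validate -> candidates -> Superconcept ->
Delta -> category -> mapping -> resource emission and stops with a typed
failure at the first hard error; everything computed up to that point stays
in the report.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional

from . import classify, fhir, superdelta
from .errors import ExpressionSyntaxError, PcebridgeError
from .expression import Expression, parse, serialize
from .fhir import CoverageStats, MappingResult, StructureMapModel
from .superdelta import Delta, SuperconceptResult
from .terminology import (
    LoadConfig,
    MrcmRule,
    Terminology,
    ValidationIssue,
    ValidationReport,
    load_mrcm,
    load_rf2,
    validate_semantics,
)

log = logging.getLogger("pcebridge")


@dataclass(frozen=True)
class PipelineConfig:
    terminology_dir: str
    mrcm_path: str
    categories_path: str
    maps_dir: str
    profile_set: str = "nashp-like"
    namespace: str = "http://snomed.info/id/"
    output_format: str = "json"  # json | text
    check_digits: bool = False

    def validate_paths(self) -> None:
        for path in (self.terminology_dir, self.mrcm_path, self.categories_path, self.maps_dir):
            if not os.path.exists(path):
                raise PcebridgeError(f"configured path does not exist: {path}")


@dataclass
class DecompositionReport:
    input_expression: str
    canonical_expression: Optional[str] = None
    validation: Optional[ValidationReport] = None
    candidates: Optional[classify.CandidateSet] = None
    scores: Optional[SuperconceptResult] = None
    superconcept: Optional[str] = None
    delta: Optional[Delta] = None
    category: Optional[str] = None
    mapping: Optional[MappingResult] = None
    resources: list = field(default_factory=list)
    failed_stage: Optional[str] = None

    def to_dict(self) -> dict:
        out: dict = {"inputExpression": self.input_expression}
        if self.canonical_expression is not None:
            out["canonicalExpression"] = self.canonical_expression
        if self.validation is not None:
            out["validation"] = {
                "ok": self.validation.ok,
                "issues": [
                    {
                        "severity": i.severity,
                        "code": i.code,
                        "message": i.message,
                        "element": i.element,
                    }
                    for i in self.validation.issues
                ],
            }
        if self.candidates is not None:
            out["candidates"] = {
                "ids": sorted(self.candidates.candidates, key=int),
                "equivalentTo": self.candidates.equivalent_to,
            }
        if self.scores is not None:
            out["scores"] = [
                {
                    "candidate": s.candidate_id,
                    "nonshared": s.nonshared,
                    "union": s.union,
                    "similarity": None if math.isinf(s.value) else round(s.value, 2),
                }
                for s in self.scores.scores
            ]
            out["superconcept"] = self.scores.chosen
            out["tieBreakUsed"] = self.scores.tie_break_used
        if self.delta is not None:
            out["delta"] = sorted([list(edge) for edge in self.delta.edges])
        if self.category is not None:
            out["category"] = self.category
        if self.mapping is not None:
            out["mapping"] = {
                "bindings": [
                    {"path": b.path, "code": b.code, "display": b.display, "source": b.source}
                    for b in self.mapping.bindings
                ],
                "unmapped": sorted([list(edge) for edge in self.mapping.unmapped]),
                "profiles": self.mapping.profiles,
            }
        if self.resources:
            out["resources"] = self.resources
        if self.failed_stage is not None:
            out["failedStage"] = self.failed_stage
        return out

    def to_text(self) -> str:
        lines = [f"expression: {self.canonical_expression or self.input_expression}"]
        if self.validation is not None:
            lines.append(f"validation: {'ok' if self.validation.ok else 'FAILED'}")
            for issue in self.validation.issues:
                lines.append(f"  [{issue.severity}] {issue.code}: {issue.message}")
        if self.candidates is not None:
            lines.append(
                "candidates: " + ", ".join(sorted(self.candidates.candidates, key=int))
            )
            if self.candidates.equivalent_to:
                lines.append(f"equivalent to: {self.candidates.equivalent_to}")
        if self.scores is not None:
            for s in self.scores.scores:
                value = "inf" if math.isinf(s.value) else f"{s.value:.2f}"
                lines.append(
                    f"  {s.candidate_id}: nonshared={s.nonshared} union={s.union} sim={value}"
                )
            lines.append(f"superconcept: {self.scores.chosen}")
        if self.delta is not None:
            lines.append(
                "delta: " + (", ".join(f"{a}={v}" for a, v in sorted(self.delta.edges)) or "(empty)")
            )
        if self.category is not None:
            lines.append(f"category: {self.category}")
        if self.mapping is not None:
            for b in self.mapping.bindings:
                lines.append(f"  {b.path} <- {b.code} |{b.display}|")
            for a, v in sorted(self.mapping.unmapped):
                lines.append(f"  unmapped: {a}={v}")
        if self.failed_stage:
            lines.append(f"failed at stage: {self.failed_stage}")
        return "\n".join(lines)


class Pipeline:
    """Loaded configuration: terminology, concept model, categories, maps."""

    def __init__(self, config: PipelineConfig):
        config.validate_paths()
        self.config = config
        self.terminology: Terminology = load_rf2(
            config.terminology_dir, LoadConfig(check_digits=config.check_digits)
        )
        self.mrcm_rules: list[MrcmRule] = load_mrcm(config.mrcm_path)
        self.categories = fhir.load_categories(config.categories_path, self.terminology)
        self.maps: list[StructureMapModel] = fhir.load_structuremap_dir(config.maps_dir)

    # -- decomposition ---------------------------------------------------

    def decompose(self, expression_text: str, patient: str | None = None) -> DecompositionReport:
        report = DecompositionReport(input_expression=expression_text)
        try:
            expr = parse(expression_text)
        except ExpressionSyntaxError as exc:
            report.validation = ValidationReport(
                (ValidationIssue("error", "syntax-error", str(exc), "expression"),)
            )
            report.failed_stage = "validation"
            return report
        report.canonical_expression = serialize(expr)
        log.info("decompose: %s", report.canonical_expression)
        report.validation = validate_semantics(self.terminology, self.mrcm_rules, expr)
        if not report.validation.ok:
            report.failed_stage = "validation"
            return report

        report.candidates = classify.superconcept_candidates(self.terminology, expr)
        log.info("candidates: %s", sorted(report.candidates.candidates, key=int))
        report.scores = superdelta.score_candidates(self.terminology, expr, report.candidates)
        report.superconcept = report.scores.chosen
        report.delta = superdelta.compute_delta(self.terminology, expr, report.superconcept)

        category = fhir.assign_category(
            self.terminology, expr, self.categories, superconcept=report.superconcept
        )
        report.category = category.id
        smap = fhir.select_map(self.maps, category.id, self.config.profile_set)
        report.mapping = fhir.apply_mapping(
            smap, report.superconcept, report.delta, self.terminology
        )
        context = {"patient": patient} if patient else None
        report.resources = fhir.emit_resources(
            report.mapping, context=context, original_expression=report.canonical_expression
        )
        return report

    # -- recomposition ---------------------------------------------------

    def _map_for_resources(self, resources: list[dict]) -> StructureMapModel:
        for doc in resources:
            for tag in doc.get("meta", {}).get("tag", []):
                if tag.get("system") == fhir.CATEGORY_TAG and "|" in tag.get("code", ""):
                    category_id, profile_set = tag["code"].split("|", 1)
                    return fhir.select_map(self.maps, category_id, profile_set)
        # fall back: the configured profile set's map whose Superconcept path is populated
        for smap in self.maps:
            if smap.profile_set_id != self.config.profile_set:
                continue
            bindings = fhir.extract_bindings(resources, smap)
            if any(b.path == smap.superconcept_rule.target_path for b in bindings):
                return smap
        raise PcebridgeError("cannot determine the governing StructureMap for these resources")

    def recompose_resources(
        self, resources: list[dict], original: str | None = None
    ) -> tuple[Expression, Optional[str]]:
        smap = self._map_for_resources(resources)
        bindings = fhir.extract_bindings(resources, smap)
        expr = fhir.recompose(bindings, smap, self.terminology, self.mrcm_rules)
        verdict = None
        if original is not None:
            verdict = classify.subsumption_verdict(
                self.terminology, parse(original), expr
            )
        return expr, verdict

    def recompose_files(
        self, paths: list[str], original: str | None = None
    ) -> tuple[Expression, Optional[str]]:
        resources = []
        for path in paths:
            with open(path, "r", encoding="utf-8") as fh:
                resources.append(json.load(fh))
        return self.recompose_resources(resources, original)

    # -- coverage --------------------------------------------------------

    def coverage(self) -> CoverageStats:
        element_counts = {c.id: list(c.attributes) for c in self.categories}
        return fhir.coverage_report(self.maps, element_counts)


def coverage_text(stats: CoverageStats) -> str:
    lines = ["category  profile-set  total  mappable  unmappable  via-extension  direct%  with-ext%"]
    for row in stats.rows:
        lines.append(
            f"{row.category_id}  {row.profile_set_id}  {row.total_elements}  "
            f"{row.mappable}  {row.unmappable}  {row.via_extension}  "
            f"{row.direct_pct}%  {row.with_extension_pct}%"
        )
    lines.append(
        f"aggregate direct coverage: {stats.direct_pct}% "
        f"(rows {stats.min_direct_pct}%..{stats.max_direct_pct}%)"
    )
    lines.append(
        f"aggregate with-extension coverage: {stats.with_extension_pct}% "
        f"(rows {stats.min_with_extension_pct}%..{stats.max_with_extension_pct}%)"
    )
    return "\n".join(lines)
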