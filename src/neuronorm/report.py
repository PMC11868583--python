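"""Individualized report assembly and rendering.

Each report binds the three headline outputs for one participant — brain age
(predicted vs chronological and the gap), the overall Outlier Index Score
with its category, and the region-level deviations ranked by magnitude —
plus model/version metadata and any harmonization out-of-range flags.
Reports render losslessly to JSON or to a three-section markdown document.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .outliers import DEFAULT_CUTOFFS, categorize_ois


@dataclass
class IndividualReport:
    id: str
    chronological_age: float | None
    predicted_brain_age: float | None
    raw_bag: float | None
    normalized_bag: float | None
    overall_ois: float | None
    category: str | None
    top_regions: list[dict] = field(default_factory=list)   # ranked by |OIS|
    all_regions: list[dict] = field(default_factory=list)
    out_of_range_iqms: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def build_report(participant_id: str, *, chronological_age=None,
                 predicted_age=None, raw_bag=None, normalized_bag=None,
                 overall_ois=None, roi_ois=None, roi_names=None,
                 cutoffs=DEFAULT_CUTOFFS, top_n: int = 10,
                 out_of_range_iqms=(), metadata=None) -> IndividualReport:
    """Assemble a deterministic individual report; missing blocks stay null."""
    category = None
    if overall_ois is not None:
        category = str(categorize_ois(float(overall_ois), cutoffs))
    regions: list[dict] = []
    if roi_ois is not None:
        values = np.asarray(roi_ois, dtype=float)
        names = list(roi_names) if roi_names is not None else [
            f"roi_{j}" for j in range(len(values))]
        if len(names) != len(values):
            raise ValueError("roi_names and roi_ois lengths differ")
        # rank by |OIS| descending; ties broken by name for stable output
        order = sorted(range(len(values)), key=lambda j: (-abs(values[j]), names[j]))
        regions = [{"roi": names[j], "ois": float(values[j]), "rank": r + 1}
                   for r, j in enumerate(order)]
    meta = {"tool": "neuronorm", "version": __version__, "cutoffs": list(cutoffs)}
    meta.update(metadata or {})
    return IndividualReport(
        id=str(participant_id),
        chronological_age=None if chronological_age is None else float(chronological_age),
        predicted_brain_age=None if predicted_age is None else float(predicted_age),
        raw_bag=None if raw_bag is None else float(raw_bag),
        normalized_bag=None if normalized_bag is None else float(normalized_bag),
        overall_ois=None if overall_ois is None else float(overall_ois),
        category=category,
        top_regions=regions[:min(top_n, len(regions))],
        all_regions=regions,
        out_of_range_iqms=list(out_of_range_iqms),
        metadata=meta,
    )


def render_report(report: IndividualReport, fmt: str = "json") -> str:
    """Render to a JSON (lossless) or markdown string."""
    if fmt == "json":
        return json.dumps(asdict(report), indent=1, sort_keys=True)
    if fmt == "markdown":
        return _render_markdown(report)
    raise ValueError(f"unknown report format {fmt!r}; use 'json' or 'markdown'")


def report_from_json(text: str) -> IndividualReport:
    return IndividualReport(**json.loads(text))


def _fmt(value, digits=2) -> str:
    return "n/a" if value is None else f"{value:.{digits}f}"


def _render_markdown(r: IndividualReport) -> str:
    lines = [f"# Normative report for {r.id}", ""]
    lines += ["## Brain Age", ""]
    lines.append(f"- Chronological age: {_fmt(r.chronological_age, 1)} years")
    lines.append(f"- Predicted brain age: {_fmt(r.predicted_brain_age, 1)} years")
    if r.raw_bag is not None:
        trend = "accelerated" if r.raw_bag > 0 else ("delayed" if r.raw_bag < 0 else "matched")
        lines.append(f"- Brain-age gap: {r.raw_bag:+.1f} years "
                     f"(normalized {_fmt(r.normalized_bag)}) — {trend} ageing")
    else:
        lines.append("- Brain-age gap: n/a")
    lines += ["", "## Outlier Index Score", ""]
    lines.append(f"- Overall OIS: {_fmt(r.overall_ois)}")
    lines.append(f"- Category: {r.category or 'n/a'}")
    lines += ["", "## Regional deviations from the norm", ""]
    if r.top_regions:
        lines.append("| Rank | Region | OIS |")
        lines.append("| --- | --- | --- |")
        for entry in r.top_regions:
            lines.append(f"| {entry['rank']} | {entry['roi']} | {entry['ois']:.2f} |")
    else:
        lines.append("No regional scores available.")
    lines += ["", f"_Generated by neuronorm {r.metadata.get('version', '?')}_", ""]
    return "\n".join(lines)
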