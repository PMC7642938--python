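"""Activity scoring (pluggable) and assembly/serialization of the
per-guide design table.

The bundled ``gc_balance`` scorer is a placeholder heuristic — it rewards
spacers near 50% GC and knows nothing about position-specific sequence
preferences.  Scores from an external activity model can be injected via
the ``table`` scorer, which passes through a user-supplied spacer->score
TSV unchanged.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from .popcov import CoverageReport
from .seqcore import GuideCandidate, gc_percent

logger = logging.getLogger(__name__)

#: Fixed output column order for the design table.
TABLE_COLUMNS = [
    "spacer",
    "pam_site",
    "activity_score",
    "gc_percent",
    "chromosome",
    "position",
    "strand",
    "position_in_gene",
    "mismatches_allowed",
    "offsite_matches",
    "human_hits",
    "strain_coverage",
]


class ActivityScorer:
    """A deterministic mapping (spacer, observed PAM) -> score."""

    def __init__(self, scorer_id: str, score_fn: Callable[[str, str], float]) -> None:
        self.scorer_id = scorer_id
        self._fn = score_fn

    def __call__(self, spacer: str, pam_observed: str) -> float:
        return self._fn(spacer, pam_observed)


def _gc_balance(spacer: str, pam_observed: str) -> float:
    """1 at 50% GC, falling linearly to 0 at 0% or 100% GC."""
    gc = gc_percent(spacer) / 100.0
    return 1.0 - abs(gc - 0.5) * 2.0


def load_score_table(path) -> dict[str, float]:
    """Read a two-column, headerless ``spacer<TAB>score`` TSV."""
    path = Path(path)
    table: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected spacer<TAB>score")
        table[parts[0].upper()] = float(parts[1])
    return table


def make_table_scorer(path) -> ActivityScorer:
    table = load_score_table(path)

    def fn(spacer: str, pam_observed: str) -> float:
        key = spacer.upper()
        if key not in table:
            raise KeyError(f"spacer {spacer!r} absent from score table")
        return table[key]

    return ActivityScorer("table", fn)


def get_scorer(scorer_id: str, table_path=None) -> ActivityScorer:
    """Resolve a scorer by id: ``gc_balance`` or ``table`` (+ TSV path)."""
    if scorer_id == "gc_balance":
        return ActivityScorer("gc_balance", _gc_balance)
    if scorer_id == "table":
        if table_path is None:
            raise ValueError("table scorer requires a score-table path")
        return make_table_scorer(table_path)
    raise ValueError(f"unknown scorer {scorer_id!r}")


def score_activity(guide: GuideCandidate, scorer: ActivityScorer) -> float:
    return scorer(guide.spacer, guide.pam_observed)


@dataclass
class DesignRow:
    """One fully-joined result row per guide candidate."""

    spacer: str
    pam_site: str
    activity_score: float
    gc_percent: float
    chromosome: str
    position: int
    strand: str
    position_in_gene: Optional[int]
    mismatches_allowed: int
    offsite_matches: Optional[int]
    human_hits: Optional[str]
    strain_coverage: Optional[int]
    covered: list[str] = field(default_factory=list)
    not_covered: list[str] = field(default_factory=list)


def build_design_table(
    guides: Sequence[GuideCandidate],
    scorer: ActivityScorer,
    coverage_reports: Optional[dict[GuideCandidate, CoverageReport]] = None,
    offtarget_counts: Optional[dict[GuideCandidate, int]] = None,
    biosafety_flags: Optional[dict[GuideCandidate, bool]] = None,
    mismatches_allowed: int = 0,
) -> list[DesignRow]:
    """Join all per-guide results into one row per guide.

    A pure join: every optional input must be keyed by exactly the guides
    given (key mismatch raises), and permuting input order never changes
    row content.  Rows are sorted by descending activity score, ties by
    ascending position (stable).  Guides with zero covered strains are
    retained.
    """
    for name, mapping in (
        ("coverage_reports", coverage_reports),
        ("offtarget_counts", offtarget_counts),
        ("biosafety_flags", biosafety_flags),
    ):
        if mapping is not None and set(mapping) != set(guides):
            raise ValueError(f"{name} keys do not match the guide list")

    rows: list[DesignRow] = []
    for g in guides:
        cov = coverage_reports.get(g) if coverage_reports else None
        bio = biosafety_flags.get(g) if biosafety_flags else None
        rows.append(
            DesignRow(
                spacer=g.spacer,
                pam_site=g.pam_observed,
                activity_score=score_activity(g, scorer),
                gc_percent=gc_percent(g.spacer),
                chromosome=g.contig,
                position=g.start,
                strand=g.strand,
                position_in_gene=g.gene_offset,
                mismatches_allowed=mismatches_allowed,
                offsite_matches=offtarget_counts.get(g) if offtarget_counts else None,
                human_hits=None if bio is None else ("Yes" if bio else "No"),
                strain_coverage=cov.n_covered if cov else None,
                covered=list(cov.covered) if cov else [],
                not_covered=list(cov.not_covered) if cov else [],
            )
        )
    rows.sort(key=lambda r: (-r.activity_score, r.position))
    return rows


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.4f}".rstrip("0").rstrip(".")
    return str(value)


def write_table(
    rows: Sequence[DesignRow],
    format: str = "tsv",
    metadata: Optional[dict] = None,
) -> str:
    """Serialize design rows as TSV (fixed header order) or JSON.

    The JSON document carries a ``metadata`` block (run provenance) and a
    ``guides`` array whose objects include the covered / not_covered
    strain identity lists; TSV echoes metadata as leading '#' lines.
    An empty row list yields a header-only TSV.
    """
    if format == "tsv":
        lines = []
        if metadata:
            for k in sorted(metadata):
                lines.append(f"# {k}={metadata[k]}")
        lines.append("\t".join(TABLE_COLUMNS))
        for r in rows:
            lines.append(
                "\t".join(_fmt(getattr(r, col)) for col in TABLE_COLUMNS)
            )
        return "\n".join(lines) + "\n"
    if format == "json":
        doc = {
            "metadata": metadata or {},
            "guides": [
                {
                    **{col: getattr(r, col) for col in TABLE_COLUMNS},
                    "covered": r.covered,
                    "not_covered": r.not_covered,
                }
                for r in rows
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=False) + "\n"
    raise ValueError(f"unknown format {format!r}")


def read_table_tsv(text: str) -> list[DesignRow]:
    """Parse a TSV produced by :func:`write_table` back into rows
    (identity lists are not carried by the TSV format)."""
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    if header != TABLE_COLUMNS:
        raise ValueError("unexpected TSV header")
    rows = []
    for line in lines[1:]:
        vals = dict(zip(header, line.split("\t")))
        rows.append(
            DesignRow(
                spacer=vals["spacer"],
                pam_site=vals["pam_site"],
                activity_score=float(vals["activity_score"]),
                gc_percent=float(vals["gc_percent"]),
                chromosome=vals["chromosome"],
                position=int(vals["position"]),
                strand=vals["strand"],
                position_in_gene=int(vals["position_in_gene"]) if vals["position_in_gene"] else None,
                mismatches_allowed=int(vals["mismatches_allowed"]),
                offsite_matches=int(vals["offsite_matches"]) if vals["offsite_matches"] else None,
                human_hits=vals["human_hits"] or None,
                strain_coverage=int(vals["strain_coverage"]) if vals["strain_coverage"] else None,
            )
        )
    return rows
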