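"""Multi-platform CNV consensus calling.

Per-platform call sets are QC-filtered, control/case pairs are compared to
find acquired events, calls from different platforms describing the same
region (containment rule: one interval contains the other) are merged into
consensus events, and an event is flagged significant when supported by at
least two platforms.

Coordinates are 0-based half-open (BED) internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

__all__ = [
    "CnvCall",
    "ConsensusEvent",
    "PlatformRules",
    "filter_calls",
    "same_event",
    "pair_compare",
    "build_consensus",
    "annotate_event",
    "calls_from_frame",
]

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


@dataclass(frozen=True)
class CnvCall:
    """A single-platform CNV interval with its QC metrics."""

    chrom: str
    start: int
    end: int
    type: str  # gain | loss
    platform: str  # aCGH | SNP | CytoScanHD | WES
    sample: str
    log2ratio: Optional[float] = None
    n_markers: Optional[int] = None
    call_prob: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if self.type not in ("gain", "loss"):
            raise ValueError(f"type must be gain or loss, got {self.type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusEvent:
    """A cross-platform merged CNV event."""

    chrom: str
    outer: Tuple[int, int]  # union of member intervals
    core: Tuple[int, int]  # intersection of member intervals
    type: str
    support: Set[str]
    member_calls: List[CnvCall]
    acquired: bool = False
    significant: bool = False
    genes: List[str] = field(default_factory=list)
    in_core_region: bool = False
    candidate_hits: List[str] = field(default_factory=list)


@dataclass
class PlatformRules:
    """QC filter thresholds, one attribute block per platform.

    Defaults follow common array/exome practice: SNP arrays need a 5 kb
    minimum size and 5 markers; CytoScan segments must exceed 100 kb and 25
    markers; WES calls need call probability >= 0.9 and |log2ratio| >= 0.5.
    Sex-chromosome (and optionally centromeric) calls are false positives on
    every platform.
    """

    snp_min_length: int = 5_000
    snp_min_markers: int = 5
    cytoscan_min_length: int = 100_000
    cytoscan_min_markers: int = 25
    wes_min_call_prob: float = 0.9
    wes_min_abs_log2ratio: float = 0.5
    exclude_sex_chroms: bool = True
    centromeres: Optional[pd.DataFrame] = None  # BED-like: chrom, start, end

    KNOWN_PLATFORMS = ("aCGH", "SNP", "CytoScanHD", "WES")


def _require(call: CnvCall, attr: str):
    v = getattr(call, attr)
    if v is None or (isinstance(v, float) and v != v):
        raise ValueError(
            f"call on {call.platform} missing required metric {attr!r}"
        )
    return v


def _overlaps_centromere(call: CnvCall, centromeres: pd.DataFrame) -> bool:
    sub = centromeres[centromeres["chrom"] == call.chrom]
    return bool(
        ((sub["start"] < call.end) & (sub["end"] > call.start)).any()
    )


def filter_calls(
    calls: Iterable[CnvCall], rules: Optional[PlatformRules] = None
) -> List[CnvCall]:
    """Apply per-platform QC rules; order of surviving calls is preserved."""
    rules = rules or PlatformRules()
    out: List[CnvCall] = []
    for call in calls:
        if call.platform not in PlatformRules.KNOWN_PLATFORMS:
            raise ValueError(f"unknown platform {call.platform!r}")
        if rules.exclude_sex_chroms and call.chrom in SEX_CHROMS:
            continue
        if rules.centromeres is not None and _overlaps_centromere(call, rules.centromeres):
            continue
        if call.platform == "SNP":
            if call.length < rules.snp_min_length:
                continue
            if _require(call, "n_markers") < rules.snp_min_markers:
                continue
        elif call.platform == "CytoScanHD":
            if call.length <= rules.cytoscan_min_length:
                continue
            if _require(call, "n_markers") <= rules.cytoscan_min_markers:
                continue
        elif call.platform == "WES":
            if _require(call, "call_prob") < rules.wes_min_call_prob:
                continue
            if abs(_require(call, "log2ratio")) < rules.wes_min_abs_log2ratio:
                continue
        # aCGH: only the global exclusions apply (segmentation QC is upstream)
        out.append(call)
    return out


def _contains(a: CnvCall, b: CnvCall) -> bool:
    return a.start <= b.start and a.end >= b.end


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def same_event(
    a: CnvCall,
    b: CnvCall,
    min_reciprocal_overlap: Optional[float] = None,
) -> bool:
    """True iff two calls describe the same event.

    Same chromosome, same type, and one interval contains the other.  An
    optional reciprocal-overlap fallback (off by default) additionally
    accepts pairs whose reciprocal overlap reaches the given threshold.
    Symmetric by construction.
    """
    if a.chrom != b.chrom or a.type != b.type:
        return False
    if _contains(a, b) or _contains(b, a):
        return True
    if min_reciprocal_overlap is not None:
        return _reciprocal_overlap(a, b) >= min_reciprocal_overlap
    return False


def pair_compare(
    control_calls: Sequence[CnvCall],
    case_calls: Sequence[CnvCall],
) -> Dict[str, List[CnvCall]]:
    """Partition a control/case pair into acquired / shared / lost calls.

    A case call is *acquired* when no same-platform control call is
    ``same_event`` with it, *shared* otherwise; a control call with no case
    partner is *lost*.  Each call is matched to at most one partner from the
    same platform, greedily by largest reciprocal overlap (ties: leftmost
    start).
    """
    for name, group in (("control", control_calls), ("case", case_calls)):
        samples = {c.sample for c in group}
        if len(samples) > 1:
            raise ValueError(f"{name} list mixes samples: {sorted(samples)}")

    candidates = []
    for i, cs in enumerate(case_calls):
        for j, ct in enumerate(control_calls):
            if cs.platform == ct.platform and same_event(cs, ct):
                candidates.append((-_reciprocal_overlap(cs, ct), min(cs.start, ct.start), i, j))
    candidates.sort()
    matched_case: Set[int] = set()
    matched_ctrl: Set[int] = set()
    for _, _, i, j in candidates:
        if i not in matched_case and j not in matched_ctrl:
            matched_case.add(i)
            matched_ctrl.add(j)
    return {
        "acquired": [c for i, c in enumerate(case_calls) if i not in matched_case],
        "shared": [c for i, c in enumerate(case_calls) if i in matched_case],
        "lost": [c for j, c in enumerate(control_calls) if j not in matched_ctrl],
    }


def build_consensus(
    calls: Sequence[CnvCall],
    min_support: int = 2,
    min_reciprocal_overlap: Optional[float] = None,
) -> List[ConsensusEvent]:
    """Merge calls into consensus events (connected components of same_event).

    outer = union of member intervals, core = their intersection; an event is
    significant when supported by >= ``min_support`` distinct platforms.
    Output order is deterministic: (chromosome, outer start, type).
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if same_event(calls[i], calls[j], min_reciprocal_overlap):
                g.add_edge(i, j)
    events: List[ConsensusEvent] = []
    for comp in nx.connected_components(g):
        members = [calls[i] for i in sorted(comp)]
        outer = (min(c.start for c in members), max(c.end for c in members))
        core_start = max(c.start for c in members)
        core_end = min(c.end for c in members)
        if core_end < core_start:  # possible for containment chains a⊆b⊇c
            core_start = core_end = core_start
        support = {c.platform for c in members}
        events.append(
            ConsensusEvent(
                chrom=members[0].chrom,
                outer=outer,
                core=(core_start, core_end),
                type=members[0].type,
                support=support,
                member_calls=members,
                significant=len(support) >= min_support,
            )
        )
    events.sort(key=lambda e: (e.chrom, e.outer[0], e.outer[1], e.type))
    return events


def annotate_event(
    event: ConsensusEvent,
    gene_model: pd.DataFrame,
    candidate_region: Optional[Tuple[str, int, int]] = None,
    candidate_genes: Sequence[str] = (),
) -> ConsensusEvent:
    """Attach overlapping genes and candidate-region flags to an event.

    A gene overlaps when it shares >= 1 bp with the outer interval
    (half-open).  ``candidate_region`` is (chrom, start, end) of the
    configured core amplicon.
    """
    sub = gene_model[gene_model["chrom"] == event.chrom]
    if sub.empty:
        warnings.warn(
            f"chromosome {event.chrom} absent from gene model; no genes annotated"
        )
        event.genes = []
    else:
        hit = sub[(sub["start"] < event.outer[1]) & (sub["end"] > event.outer[0])]
        event.genes = sorted(hit["gene"])
    if candidate_region is not None:
        chrom, start, end = candidate_region
        event.in_core_region = (
            event.chrom == chrom and event.outer[0] < end and event.outer[1] > start
        )
    event.candidate_hits = sorted(set(candidate_genes) & set(event.genes))
    return event


# ---------------------------------------------------------------------------
# frame <-> dataclass interop
# ---------------------------------------------------------------------------

def calls_from_frame(df: pd.DataFrame) -> List[CnvCall]:
    """Build CnvCall objects from a call table (as written by the simulator)."""
    calls = []
    for row in df.itertuples(index=False):
        prob = getattr(row, "call_prob", None)
        markers = getattr(row, "n_markers", None)
        calls.append(
            CnvCall(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                type=row.type,
                platform=row.platform,
                sample=row.sample,
                log2ratio=float(row.log2ratio) if row.log2ratio == row.log2ratio else None,
                n_markers=int(markers) if markers == markers and markers is not None else None,
                call_prob=float(prob) if prob is not None and prob == prob else None,
            )
        )
    return calls


def events_to_frame(events: Sequence[ConsensusEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            dict(
                chrom=e.chrom,
                outer_start=e.outer[0],
                outer_end=e.outer[1],
                core_start=e.core[0],
                core_end=e.core[1],
                type=e.type,
                support=",".join(sorted(e.support)),
                n_platforms=len(e.support),
                significant=e.significant,
                acquired=e.acquired,
                in_core_region=e.in_core_region,
                genes=",".join(e.genes),
                candidate_hits=",".join(e.candidate_hits),
            )
        )
    return pd.DataFrame(rows)
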