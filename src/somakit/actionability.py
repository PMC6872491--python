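"""Clinical actionability matching and ranking.

Driver events are matched against a knowledgebase in a common evidence
model (biomarker, drug, evidence level A/B, sensitivity/resistance
direction, disease-ontology id).  A match is on-label when the sample's
tumour-type DOID equals the record's DOID or is one of its descendants.
Treatments with resistance evidence from other biomarkers in the same
sample at the same or higher evidence level are excluded; the remaining
matches rank A on-label > A off-label > B on-label > B off-label, and the
highest level is reported.  MSI samples gain a level-A match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .drivers import DriverEvent

__all__ = ["EvidenceRecord", "Match", "ActionabilityCall",
           "load_knowledgebase", "match_actionable_events",
           "rank_and_report"]

_LEVELS = ("A", "B")
_DROPPED_LEVELS = ("C", "D", "E")


@dataclass(frozen=True)
class EvidenceRecord:
    gene: str | None                # None for sample-level biomarkers (MSI)
    event_class: str                # point|amplification|...|msi
    detail: str | None              # exact-variant specificity when set
    drug: str
    level: str                      # A | B
    direction: str                  # sensitivity | resistance
    doid: str

    def __post_init__(self):
        if self.level not in _LEVELS:
            raise ValueError(f"evidence level {self.level} not in A/B")
        if self.direction not in ("sensitivity", "resistance"):
            raise ValueError(f"unknown direction {self.direction}")


def load_knowledgebase(records: list[dict]) -> list[EvidenceRecord]:
    """Normalise raw records into the common model.

    C/D/E-level records are dropped; duplicates (identical on all fields)
    are removed; an unrecognised level token raises.
    """
    out: list[EvidenceRecord] = []
    seen = set()
    for r in records:
        level = r["level"]
        if level in _DROPPED_LEVELS:
            continue
        rec = EvidenceRecord(r.get("gene"), r["event_class"],
                             r.get("detail"), r["drug"], level,
                             r["direction"], r["doid"])
        if rec not in seen:
            seen.add(rec)
            out.append(rec)
    return out


def is_self_or_descendant(ontology: dict[str, str], child: str,
                          ancestor: str) -> bool:
    node = child
    seen = set()
    while node is not None and node not in seen:
        if node == ancestor:
            return True
        seen.add(node)
        node = ontology.get(node)
    return False


@dataclass(frozen=True)
class Match:
    record: EvidenceRecord
    event_ref: str                  # matched biomarker description
    on_label: bool
    specificity: int                # 2 exact variant, 1 gene+class

    @property
    def rank_key(self) -> tuple:
        # lower sorts better: A before B, on-label before off-label
        return (_LEVELS.index(self.record.level), 0 if self.on_label else 1)


def match_actionable_events(events: list[DriverEvent], msi_status: str,
                            knowledgebase: list[EvidenceRecord],
                            sample_doid: str | None,
                            ontology: dict[str, str]) -> list[Match]:
    """Match a sample's driver events (and MSI status) to the knowledgebase.

    All directions are matched — resistance matches feed the exclusion
    rule downstream.  A missing sample DOID degrades every match to
    off-label.
    """
    matches: list[Match] = []
    for rec in knowledgebase:
        if rec.event_class == "msi":
            if msi_status != "MSI":
                continue
            hit_ref, spec = "MSI", 1
        else:
            hit = None
            spec = 0
            for ev in events:
                if ev.gene != rec.gene or ev.event_class != rec.event_class:
                    continue
                if rec.detail is not None:
                    if ev.detail.startswith(rec.detail):
                        hit, spec = ev, 2
                        break
                else:
                    hit, spec = ev, 1
            if hit is None:
                continue
            hit_ref = f"{hit.gene}:{hit.event_class}"
        on_label = (sample_doid is not None
                    and is_self_or_descendant(ontology, sample_doid,
                                              rec.doid))
        matches.append(Match(rec, hit_ref, on_label, spec))
    return matches


@dataclass
class ActionabilityCall:
    sample: str
    best_level: str | None          # A, B or None
    best_on_label: bool | None
    treatments: list[dict] = field(default_factory=list)  # ranked
    excluded: list[dict] = field(default_factory=list)


def rank_and_report(sample_id: str, matches: list[Match]
                    ) -> ActionabilityCall:
    """Apply resistance exclusion, rank remaining matches, report the best.

    A drug is excluded when the sample carries a resistance biomarker for
    it at the same or higher evidence level as its best sensitivity
    evidence.  The reported call is the maximum over non-excluded matches,
    ranked first by evidence level and then on-label vs off-label.
    """
    res_level: dict[str, int] = {}
    for m in matches:
        if m.record.direction == "resistance":
            lvl = _LEVELS.index(m.record.level)
            res_level[m.record.drug] = min(
                res_level.get(m.record.drug, 99), lvl)
    kept, excluded = [], []
    for m in sorted((m for m in matches
                     if m.record.direction == "sensitivity"),
                    key=lambda m: (m.rank_key, -m.specificity,
                                   m.record.drug)):
        lvl = _LEVELS.index(m.record.level)
        if m.record.drug in res_level and res_level[m.record.drug] <= lvl:
            excluded.append(dict(
                drug=m.record.drug, level=m.record.level,
                reason=f"resistance evidence at level "
                       f"{_LEVELS[res_level[m.record.drug]]}"))
            continue
        kept.append(dict(drug=m.record.drug, level=m.record.level,
                         on_label=m.on_label, biomarker=m.event_ref))
    if not kept:
        return ActionabilityCall(sample_id, None, None, [], excluded)
    best = kept[0]
    return ActionabilityCall(sample_id, best["level"], best["on_label"],
                             kept, excluded)
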