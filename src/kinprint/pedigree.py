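"""Pedigree-derived expected relationships and genotype-vs-pedigree QC.

The pedigree is a directed parent graph (child -> father, child ->
mother) with optional MZ-twin annotations and a subject-to-sample
mapping.  Expected pairwise relationships come from the standard
recursive kinship coefficient

    phi(a, a) = 1/2 (1 + phi(father_a, mother_a))
    phi(a, b) = 1/2 (phi(father_a, b) + phi(mother_a, b))   (a not an ancestor of b)

mapped to degrees (phi = 2^-(d+1) for degree d), with first-degree pairs
resolved into PO vs FS by parent edges.  ``qc_report`` compares these
reported relationships against genotype-predicted ones and categorizes
every related pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .classify import RelationshipModel, classify_pair, default_model
from .fingerprint import FingerprintSet
from .metrics import PairStats, all_pairs_stats

log = logging.getLogger(__name__)

__all__ = [
    "PedigreeGraph",
    "PedigreeError",
    "DiscrepancyRecord",
    "QCReport",
    "expected_relationship",
    "kinship_coefficient",
    "qc_report",
    "read_pedigree",
    "write_pedigree",
]

RELATED_LABELS = ("ID", "PO", "FS", "D2", "D3")


class PedigreeError(ValueError):
    """Structurally invalid pedigree (cycle, >2 parents, ...)."""


@dataclass
class PedigreeGraph:
    """Family structure: parent edges, MZ twins, subject-to-sample mapping."""

    parents: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)
    sexes: dict[str, str] = field(default_factory=dict)
    mz_twins: set[frozenset] = field(default_factory=set)
    # sample id -> subject id; defaults to identity for unmapped samples
    sample_to_subject: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, (f, m) in self.parents.items():
            for p in (f, m):
                if p is not None:
                    g.add_edge(p, child)
        return g

    def _validate(self) -> None:
        g = self._graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains a cycle: {cycle}")

    def individuals(self) -> list[str]:
        ids = set(self.parents)
        for f, m in self.parents.values():
            ids.update(p for p in (f, m) if p is not None)
        return sorted(ids)

    def parents_of(self, ind: str) -> tuple[str | None, str | None]:
        return self.parents.get(ind, (None, None))

    def is_parent(self, a: str, b: str) -> bool:
        """True if a is a parent of b or b is a parent of a."""
        return a in self.parents_of(b) or b in self.parents_of(a)

    def are_mz(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.mz_twins

    def subject_of(self, sample_id: str) -> str:
        return self.sample_to_subject.get(sample_id, sample_id)

    def _depths(self) -> dict[str, int]:
        depths: dict[str, int] = {}

        def depth(ind: str) -> int:
            if ind in depths:
                return depths[ind]
            f, m = self.parents_of(ind)
            d = 0
            if f is not None:
                d = max(d, depth(f) + 1)
            if m is not None:
                d = max(d, depth(m) + 1)
            depths[ind] = d
            return d

        for ind in self.individuals():
            depth(ind)
        return depths


def kinship_coefficient(ped: PedigreeGraph, a: str, b: str) -> float:
    """Recursive pedigree kinship phi(a, b); founders are unrelated."""
    depths = ped._depths()

    @lru_cache(maxsize=None)
    def phi(x: str | None, y: str | None) -> float:
        if x is None or y is None:
            return 0.0
        if x == y:
            f, m = ped.parents_of(x)
            return 0.5 * (1.0 + phi(f, m))
        # recurse on the deeper individual: it cannot be an ancestor of the other
        if depths.get(x, 0) < depths.get(y, 0):
            x, y = y, x
        f, m = ped.parents_of(x)
        if f is None and m is None:
            return 0.0
        return 0.5 * (phi(f, y) + phi(m, y))

    return phi(a, b)


def expected_relationship(ped: PedigreeGraph, a: str, b: str) -> str:
    """Expected relationship label for two individuals: ID/PO/FS/D2/D3/UN.

    Same subject or annotated MZ twins -> ID; a parent edge -> PO; shared
    parents (both) -> FS; otherwise degree from the kinship coefficient
    (1/8 -> D2, 1/16 -> D3, more distant -> UN).  Compound relationships
    whose total phi is not a power of two are classified by the nearest
    degree with a warning.
    """
    if a == b or ped.subject_of(a) == ped.subject_of(b):
        return "ID"
    if ped.are_mz(a, b):
        return "ID"
    if ped.is_parent(a, b):
        return "PO"
    fa, ma = ped.parents_of(a)
    fb, mb = ped.parents_of(b)
    if fa is not None and ma is not None and (fa, ma) == (fb, mb):
        return "FS"
    phi = kinship_coefficient(ped, a, b)
    if phi <= 0.0:
        return "UN"
    for degree, value in ((1, 0.25), (2, 0.125), (3, 0.0625)):
        if abs(phi - value) < 1e-9:
            if degree == 1:
                # first-degree phi without parent edge or shared parents:
                # compound relationship (e.g. double first cousins)
                log.warning("pair %s/%s has compound relationship (phi=%.4f)", a, b, phi)
                return "D2" if phi < 0.25 else "FS"
            return {2: "D2", 3: "D3"}[degree]
    log.warning("pair %s/%s: compound kinship phi=%.4f; using nearest degree", a, b, phi)
    if phi >= 3 / 16:
        return "FS"
    if phi >= 3 / 32:
        return "D2"
    if phi >= 3 / 64:
        return "D3"
    return "UN"


CATEGORIES = (
    "confirmed",
    "type_mismatch",
    "unreported_related",
    "reported_but_unrelated",
    "duplicate_unreported",
)


@dataclass(frozen=True)
class DiscrepancyRecord:
    id_a: str
    id_b: str
    reported: str  # expected label from pedigree/mapping, or "UN"
    predicted: str
    category: str
    stats: PairStats
    note: str = ""


@dataclass
class QCReport:
    records: list[DiscrepancyRecord]
    orphan_samples: list[str]
    summary: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id_a": r.id_a,
                    "id_b": r.id_b,
                    "reported": r.reported,
                    "predicted": r.predicted,
                    "category": r.category,
                    "agmr": round(r.stats.agmr, 6) if r.stats.agmr is not None else "",
                    "hgmr": round(r.stats.hgmr, 6) if r.stats.hgmr is not None else "",
                    "note": r.note,
                }
                for r in self.records
            ]
        )


def _categorize(reported: str, predicted: str) -> str:
    rep_rel = reported in RELATED_LABELS
    pred_rel = predicted in RELATED_LABELS
    if reported == predicted:
        return "confirmed"
    if rep_rel and pred_rel:
        return "type_mismatch"
    if pred_rel and not rep_rel:
        return "duplicate_unreported" if predicted == "ID" else "unreported_related"
    return "reported_but_unrelated"


def _note_for(reported: str, predicted: str, stats: PairStats) -> str:
    agmr = stats.agmr
    if agmr is None or reported != "ID":
        return ""
    # reported identical/MZ but genotypes disagree like siblings or strangers
    if 0.25 <= agmr <= 0.42:
        return "AGMR near full-sibling expectation; probably DZ twins"
    if agmr > 0.45:
        return "AGMR near unrelated expectation; samples likely mislabelled"
    return ""


def qc_report(
    fps: FingerprintSet,
    ped: PedigreeGraph,
    model: RelationshipModel | None = None,
    min_compared: int = 64,
) -> QCReport:
    """Compare pedigree-reported and genotype-predicted relationships.

    Every sample pair that is reported related or predicted related
    appears exactly once.  Samples that cannot be mapped into the
    pedigree are listed as orphans (compared as unrelated subjects, not
    fatal).
    """
    if model is None:
        model = default_model()
    ped_inds = set(ped.individuals())
    known = ped_inds | set(ped.sample_to_subject)
    orphans = [sid for sid in fps.ids if sid not in known]
    if orphans:
        log.warning("%d fingerprint samples absent from pedigree/mapping", len(orphans))

    records: list[DiscrepancyRecord] = []
    summary = {c: 0 for c in CATEGORIES}
    for st in all_pairs_stats(fps, min_compared=min_compared):
        if st.n_compared < min_compared:
            continue
        sa = ped.subject_of(st.id_a)
        sb = ped.subject_of(st.id_b)
        if sa == sb:
            reported = "ID"
        elif sa in ped_inds and sb in ped_inds:
            reported = expected_relationship(ped, sa, sb)
        else:
            reported = "UN"
        predicted, _ = classify_pair(st, model)
        if reported not in RELATED_LABELS and predicted not in RELATED_LABELS:
            continue
        category = _categorize(reported, predicted)
        records.append(
            DiscrepancyRecord(
                st.id_a, st.id_b, reported, predicted, category, st,
                note=_note_for(reported, predicted, st),
            )
        )
        summary[category] += 1
    return QCReport(records=records, orphan_samples=orphans, summary=summary)


def read_pedigree(
    ped_path, twin_path=None, mapping_path=None
) -> PedigreeGraph:
    """Read a PED-style TSV (family, individual, father, mother, sex).

    ``twin_path`` (optional): two columns of individual ids per MZ pair.
    ``mapping_path`` (optional): sample_id <tab> subject_id.
    """
    parents, families, sexes = {}, {}, {}
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 5:
            raise PedigreeError(f"{ped_path}: expected >=5 columns, got {len(f)}")
        fam, ind, father, mother, sex = f[:5]
        parents[ind] = (
            None if father == "0" else father,
            None if mother == "0" else mother,
        )
        families[ind] = fam
        sexes[ind] = {"1": "male", "2": "female"}.get(sex, "unknown")
    mz = set()
    if twin_path is not None:
        for line in Path(twin_path).read_text().splitlines():
            if line.strip():
                a, b = line.split()[:2]
                mz.add(frozenset((a, b)))
    mapping = {}
    if mapping_path is not None:
        for line in Path(mapping_path).read_text().splitlines():
            if line.strip() and not line.startswith("sample"):
                s, subj = line.split()[:2]
                mapping[s] = subj
    return PedigreeGraph(
        parents=parents, families=families, sexes=sexes, mz_twins=mz,
        sample_to_subject=mapping,
    )


def write_pedigree(ped: PedigreeGraph, path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in ped.individuals():
            f, m = ped.parents_of(ind)
            fh.write(
                f"{ped.families.get(ind, 'F0')}\t{ind}\t{f or 0}\t{m or 0}\t"
                f"{sex_code.get(ped.sexes.get(ind, 'unknown'), '0')}\n"
            )
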