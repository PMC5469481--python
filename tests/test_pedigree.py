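import numpy as np
import pytest

from kinprint.fingerprint import pack_genotypes
from kinprint.pedigree import (
    PedigreeError,
    PedigreeGraph,
    expected_relationship,
    kinship_coefficient,
    qc_report,
    read_pedigree,
    write_pedigree,
)
from kinprint.simulate import SimConfig, simulate


@pytest.fixture()
def big_family():
    """Three generations with half sibs, avuncular and cousin pairs.

    gpa x gma -> dad, aunt;  dad x mom -> kid1, kid2;  aunt x uncle -> cousin;
    mom x dad2 -> halfsib (shares only mom with kid1/kid2);
    kid1 x spouse -> grandkid (great-grandchild of gpa).
    """
    parents = {
        "gpa": (None, None), "gma": (None, None),
        "dad": ("gpa", "gma"), "aunt": ("gpa", "gma"),
        "mom": (None, None), "uncle": (None, None), "dad2": (None, None),
        "kid1": ("dad", "mom"), "kid2": ("dad", "mom"),
        "cousin": ("uncle", "aunt"),
        "halfsib": ("dad2", "mom"),
        "spouse": (None, None),
        "grandkid": ("kid1", "spouse"),
    }
    return PedigreeGraph(parents=parents)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("dad", "kid1", "PO"),
        ("kid1", "kid2", "FS"),
        ("kid1", "halfsib", "D2"),        # shared mother only
        ("gpa", "kid1", "D2"),            # grandparent-grandchild
        ("aunt", "kid1", "D2"),           # avuncular
        ("kid1", "cousin", "D3"),         # first cousins
        ("gpa", "grandkid", "D3"),        # great-grandparent
        ("mom", "aunt", "UN"),
        ("dad", "uncle", "UN"),
    ],
)
def test_expected_relationship(big_family, a, b, expected):
    assert expected_relationship(big_family, a, b) == expected
    assert expected_relationship(big_family, b, a) == expected  # symmetric


def test_kinship_values(big_family):
    assert kinship_coefficient(big_family, "kid1", "kid1") == 0.5
    assert kinship_coefficient(big_family, "kid1", "kid2") == 0.25
    assert kinship_coefficient(big_family, "kid1", "cousin") == 0.0625
    assert kinship_coefficient(big_family, "gpa", "gma") == 0.0


def test_same_subject_and_mz_are_identical(big_family):
    big_family.sample_to_subject = {"S1": "kid1", "S2": "kid1"}
    assert expected_relationship(big_family, "S1", "S2") == "ID"
    big_family.mz_twins.add(frozenset(("kid1", "kid2")))
    assert expected_relationship(big_family, "kid1", "kid2") == "ID"


def test_cycle_rejected():
    with pytest.raises(PedigreeError, match="cycle"):
        PedigreeGraph(parents={"a": ("b", None), "b": ("a", None)})


def test_pedigree_file_roundtrip(tmp_path, big_family):
    write_pedigree(big_family, tmp_path / "ped.tsv")
    back = read_pedigree(tmp_path / "ped.tsv")
    assert back.parents == {
        ind: big_family.parents_of(ind) for ind in big_family.individuals()
    }


@pytest.fixture(scope="module")
def study():
    return simulate(
        SimConfig(S=4_000, n_families=5, n_unrelated=20,
                  n_planted_duplicates=2, error_rate=0.002,
                  missing_rate=0.005, seed=31)
    )


class TestQCReport:
    def test_consistent_study_fully_confirmed(self, study):
        report = qc_report(study.fingerprints(), study.pedigree)
        assert report.summary["type_mismatch"] == 0
        assert report.summary["unreported_related"] == 0
        assert report.summary["reported_but_unrelated"] == 0
        assert report.summary["duplicate_unreported"] == 0
        assert report.summary["confirmed"] > 0
        assert report.orphan_samples == []

    def test_unmapped_duplicate_flagged(self, study):
        ped = study.pedigree
        dup_pair = sorted(next(iter(study.truth.duplicates)))
        broken = PedigreeGraph(
            parents=ped.parents, families=ped.families, sexes=ped.sexes,
            mz_twins=set(ped.mz_twins),
            sample_to_subject={
                k: v for k, v in ped.sample_to_subject.items()
                if k not in dup_pair or k == v
            },
        )
        report = qc_report(study.fingerprints(), broken)
        assert report.summary["duplicate_unreported"] >= 1
        flagged = {
            frozenset((r.id_a, r.id_b))
            for r in report.records
            if r.category == "duplicate_unreported"
        }
        assert frozenset(dup_pair) in flagged

    def test_mislabeled_sibling_is_type_mismatch(self, study):
        """Rewire one full-sib pair as half sibs in the reported pedigree."""
        ped = study.pedigree
        fs_pair = sorted(next(iter(study.truth.pairs_with("FS"))))
        a, b = fs_pair
        parents = dict(ped.parents)
        f, m = parents[b]
        parents[b] = ("phantom_father", m)  # now reported as half sibling
        broken = PedigreeGraph(
            parents=parents, families=ped.families, sexes=ped.sexes,
            sample_to_subject=dict(ped.sample_to_subject),
        )
        report = qc_report(study.fingerprints(), broken)
        mismatches = {
            frozenset((r.id_a, r.id_b)): (r.reported, r.predicted)
            for r in report.records
            if r.category == "type_mismatch"
        }
        assert mismatches.get(frozenset(fs_pair)) == ("D2", "FS")

    def test_dz_twin_note(self):
        """MZ-reported pair whose AGMR sits at the full-sibling expectation."""
        res = simulate(
            SimConfig(S=4_000, n_families=1, n_unrelated=0,
                      n_planted_duplicates=0, error_rate=0.0,
                      missing_rate=0.0, seed=8)
        )
        ped = res.pedigree
        ped.mz_twins.add(frozenset(("F1_kid1", "F1_kid2")))
        report = qc_report(res.fingerprints(), ped)
        rec = next(
            r for r in report.records
            if {r.id_a, r.id_b} == {"F1_kid1", "F1_kid2"}
        )
        assert rec.reported == "ID"
        assert "DZ twins" in rec.note
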