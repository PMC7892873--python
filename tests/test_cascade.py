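"""Variant-prioritization funnel: filters, segregation, control exclusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famrare.cascade import (
    CascadeConfig,
    classify_rarity,
    control_exclusion,
    is_deleterious,
    run_cascade,
    segregates,
)
from famrare.io import GenotypeMatrix, VariantRecord
from famrare.simulate import (
    FamilySimConfig,
    simulate_control_panel,
    simulate_family,
)

PLANTED_KEY = "12:132064747:C:T"


def _var(fclass, afs=None):
    return VariantRecord(
        "1", 100, "A", "G", functional_class=fclass, af_by_source=afs or {}
    )


@pytest.mark.parametrize(
    "fclass,afs,expected",
    [
        ("synonymous", {}, False),  # class excluded even at AF 0
        ("stop-gain", {}, True),  # protein-truncating, absent everywhere
        ("nonsynonymous", {"db": 0.0051}, False),  # just above the 0.5% bound
        ("nonsynonymous", {"db": 0.005}, True),  # boundary is inclusive
        ("splice-site", {"a": 0.001, "b": 0.02}, False),  # max over sources
        ("other", {}, False),
    ],
)
def test_deleterious_rule(fclass, afs, expected):
    assert is_deleterious(_var(fclass, afs)) is expected


@pytest.mark.parametrize(
    "afs,expected",
    [
        ({}, "novel"),  # absent from every database
        ({"a": 0.0022}, "rare"),  # 0.001 < AF < 0.005
        ({"a": 0.0005}, "ultra-rare"),
        ({"a": 0.001}, "rare"),  # boundary case, documented decision
        ({"a": 0.02}, "common"),
        ({"a": 0.0004, "b": 0.004}, "rare"),  # classed on the max
    ],
)
def test_rarity_classes(afs, expected):
    assert classify_rarity(_var("nonsynonymous", afs)) == expected


class TestSegregation:
    def _matrix(self, dosages, family_result):
        gm = family_result.genotypes
        col = np.asarray(dosages, dtype=np.int8).reshape(-1, 1)
        return GenotypeMatrix(gm.sample_ids, ["k:1:A:G"], col)

    def test_complete_cosegregation(self, family_result):
        ped = family_result.pedigree
        gm = family_result.genotypes
        dos = [
            1 if ped.member(s).affection == "affected" else 0
            for s in gm.sample_ids
        ]
        assert segregates("k:1:A:G", self._matrix(dos, family_result), ped)

    def test_carrier_unaffected_breaks_segregation(self, family_result):
        ped = family_result.pedigree
        gm = family_result.genotypes
        dos = [
            1 if ped.member(s).affection == "affected" else 0
            for s in gm.sample_ids
        ]
        dos[gm.sample_index(ped.unaffected_ids[0])] = 1
        assert not segregates("k:1:A:G", self._matrix(dos, family_result), ped)

    def test_noncarrier_affected_breaks_segregation(self, family_result):
        ped = family_result.pedigree
        gm = family_result.genotypes
        dos = [
            1 if ped.member(s).affection == "affected" else 0
            for s in gm.sample_ids
        ]
        affected_genotyped = [s for s in gm.sample_ids if ped.member(s).affection == "affected"]
        dos[gm.sample_index(affected_genotyped[0])] = 0
        assert not segregates("k:1:A:G", self._matrix(dos, family_result), ped)

    def test_missing_policy(self, family_result):
        ped = family_result.pedigree
        gm = family_result.genotypes
        dos = [
            1 if ped.member(s).affection == "affected" else 0
            for s in gm.sample_ids
        ]
        affected_genotyped = [s for s in gm.sample_ids if ped.member(s).affection == "affected"]
        dos[gm.sample_index(affected_genotyped[0])] = -1
        m = self._matrix(dos, family_result)
        assert not segregates("k:1:A:G", m, ped, missing_policy="strict")
        assert segregates("k:1:A:G", m, ped, missing_policy="ignore")

    def test_unmatched_pedigree_member_raises(self, family_result):
        ped = family_result.pedigree
        gm = GenotypeMatrix(["nobody"], ["k:1:A:G"], np.zeros((1, 1), dtype=np.int8))
        with pytest.raises(KeyError, match="missing from genotype"):
            segregates("k:1:A:G", gm, ped)

    def test_hom_alt_affected_counts_as_carrier(self, family_result):
        ped = family_result.pedigree
        gm = family_result.genotypes
        dos = [
            2 if ped.member(s).affection == "affected" else 0
            for s in gm.sample_ids
        ]
        assert segregates("k:1:A:G", self._matrix(dos, family_result), ped)


class TestControlExclusion:
    def test_counts_and_maf(self):
        dos = np.zeros((445, 1), dtype=np.int8)
        dos[0, 0] = 1
        dos[1, 0] = 1
        gm = GenotypeMatrix([f"c{i}" for i in range(445)], ["k:1:A:G"], dos)
        excluded, maf = control_exclusion("k:1:A:G", gm)
        assert excluded
        assert maf == pytest.approx(2 / 890)

    def test_absent_allele_not_excluded(self):
        gm = GenotypeMatrix(["c0"], ["k:1:A:G"], np.zeros((1, 1), dtype=np.int8))
        assert control_exclusion("k:1:A:G", gm) == (False, 0.0)

    def test_variant_not_in_matrix(self):
        gm = GenotypeMatrix(["c0"], ["other:1:A:G"], np.zeros((1, 1), dtype=np.int8))
        assert control_exclusion("k:1:A:G", gm) == (False, 0.0)

    def test_all_missing_warns_and_keeps(self):
        dos = np.full((3, 1), -1, dtype=np.int8)
        gm = GenotypeMatrix(["a", "b", "c"], ["k:1:A:G"], dos)
        with pytest.warns(UserWarning, match="missing"):
            excluded, maf = control_exclusion("k:1:A:G", gm)
        assert not excluded and np.isnan(maf)


def _family_with_controls(seed, inject_planted=False):
    res = simulate_family(FamilySimConfig(seed=seed))
    truth = res.truth.set_index("variant_key")
    afs = truth.loc[res.genotypes.variant_keys, "true_af"].to_numpy()
    controls = simulate_control_panel(
        res.variants,
        afs,
        n_controls=445,
        seed=seed,
        force_carrier=[PLANTED_KEY] if inject_planted else (),
    )
    return res, controls


def test_cascade_recovers_planted_variant():
    res, controls = _family_with_controls(seed=7)
    out = run_cascade(res.variants, res.genotypes, res.pedigree, controls)
    assert PLANTED_KEY in out.final_candidates
    counts = [out.counts[s] for s in out.stage_names]
    assert counts == sorted(counts, reverse=True)  # funnel monotone


def test_cascade_excludes_planted_when_seen_in_controls():
    """A candidate observed in healthy controls is dropped at the last stage."""
    res, controls = _family_with_controls(seed=7, inject_planted=True)
    out = run_cascade(res.variants, res.genotypes, res.pedigree, controls)
    assert PLANTED_KEY in out.surviving["segregating"]
    assert PLANTED_KEY not in out.final_candidates


def test_cascade_empty_input(family_result):
    out = run_cascade(
        [], family_result.genotypes, family_result.pedigree, None, CascadeConfig()
    )
    assert all(c == 0 for c in out.counts.values())


def test_cascade_nested_stages(family_result):
    out = run_cascade(
        family_result.variants, family_result.genotypes, family_result.pedigree
    )
    stages = out.stage_names
    for earlier, later in zip(stages, stages[1:]):
        assert out.surviving[later] <= out.surviving[earlier]


def test_filter_order_commutes():
    """Applying segregation before the deleteriousness filter yields the
    same final set (the stages are independent per-variant predicates)."""
    for seed in range(5):
        res = simulate_family(FamilySimConfig(seed=seed, n_background=80))
        deleterious_first = {
            v.key
            for v in res.variants
            if is_deleterious(v)
            and segregates(v.key, res.genotypes, res.pedigree)
        }
        segregating_first = {
            v.key
            for v in res.variants
            if segregates(v.key, res.genotypes, res.pedigree)
            and is_deleterious(v)
        }
        assert deleterious_first == segregating_first


@settings(max_examples=100, derandomize=True)
@given(
    af=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    fclass=st.sampled_from(
        ["stop-gain", "stop-loss", "nonsynonymous", "splice-site", "synonymous", "other"]
    ),
)
def test_rarity_and_deleterious_consistency(af, fclass):
    """Any variant classed common fails the deleterious AF rule, and every
    novel protein-altering variant passes it."""
    v = _var(fclass, {"db": af} if af > 0 else {})
    rarity = classify_rarity(v)
    if rarity == "common" and af > 0.005:
        assert not is_deleterious(v)
    if rarity == "novel" and fclass in (
        "stop-gain",
        "stop-loss",
        "nonsynonymous",
        "splice-site",
    ):
        assert is_deleterious(v)
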