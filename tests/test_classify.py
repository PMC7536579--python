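import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from varstrat.classify import (
    DEFAULT_RULES,
    FrequencyBand,
    RuleInput,
    Zone,
    annotate_zones,
    frequency_band,
    load_registry_fixture,
    reclassify,
    reclassify_table,
    registry_report,
)
from varstrat.io import ReferenceRole


class TestFrequencyBand:
    @pytest.mark.parametrize(
        "count,band",
        [
            (0, FrequencyBand.MODY_COMPATIBLE),
            (2, FrequencyBand.MODY_COMPATIBLE),
            (3, FrequencyBand.LOW_FREQ_T2D),
            (33, FrequencyBand.LOW_FREQ_T2D),
            (121, FrequencyBand.LOW_FREQ_T2D),
            (122, FrequencyBand.ABOVE_LOW_FREQ),
        ],
    )
    def test_band_boundaries(self, count, band):
        assert frequency_band(count) is band

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            frequency_band(-1)

    @given(count=st.integers(0, 10_000))
    def test_bands_partition_counts(self, count):
        assert frequency_band(count) in FrequencyBand


class TestAnnotateZones:
    @staticmethod
    def zones_for(assignment, roles, centroids=None):
        return annotate_zones(
            pd.Series(assignment), pd.Series(roles), centroids=centroids
        )

    def test_pure_reference_clusters(self):
        zm = self.zones_for(
            {"WT_Ile27": 0, "WT_Leu27": 0, "p.Glu508Lys": 1, "p.Pro112Leu": 2, "x": 2},
            {
                "WT_Ile27": ReferenceRole.WILD_TYPE,
                "WT_Leu27": ReferenceRole.WILD_TYPE,
                "p.Glu508Lys": ReferenceRole.T2D_REFERENCE,
                "p.Pro112Leu": ReferenceRole.MODY_REFERENCE,
                "x": ReferenceRole.NONE,
            },
        )
        assert zm.zone_of(0) is Zone.BENIGN
        assert zm.zone_of(1) is Zone.INTERMEDIATE_T2D_RISK
        assert zm.zone_of(2) is Zone.DAMAGING_MODY
        assert zm.rosters[2] == ["p.Pro112Leu"]

    def test_conflicting_roles_give_mixed(self):
        zm = self.zones_for(
            {"WT_Ile27": 0, "p.Pro112Leu": 0},
            {
                "WT_Ile27": ReferenceRole.WILD_TYPE,
                "p.Pro112Leu": ReferenceRole.MODY_REFERENCE,
            },
        )
        assert zm.zone_of(0) is Zone.MIXED

    def test_reference_free_cluster_inherits_nearest(self):
        zm = self.zones_for(
            {"WT_Ile27": 0, "a": 1, "p.Pro112Leu": 2},
            {
                "WT_Ile27": ReferenceRole.WILD_TYPE,
                "a": ReferenceRole.NONE,
                "p.Pro112Leu": ReferenceRole.MODY_REFERENCE,
            },
            centroids={0: np.array([0.0]), 1: np.array([1.0]), 2: np.array([10.0])},
        )
        assert zm.zone_of(1) is Zone.BENIGN
        assert zm.inherited[1] is True

    def test_no_references_rejected(self):
        with pytest.raises(ValueError):
            self.zones_for({"a": 0}, {"a": ReferenceRole.NONE})


def rule_input(**kw):
    defaults = dict(
        variant="p.Test1Ala",
        original_class=4,
        zone=Zone.BENIGN,
        band=FrequencyBand.LOW_FREQ_T2D,
        exon=2,
        co_occurring_pathogenic=False,
    )
    defaults.update(kw)
    return RuleInput(**defaults)


class TestRuleEngine:
    def test_benign_zone_frequency_downgrade(self):
        """A likely-pathogenic call in a benign-zone cluster with an allele
        count too high for MODY is proposed VUS (BS1-style evidence)."""
        decision = reclassify(rule_input(original_class=4, zone=Zone.BENIGN))
        assert decision.proposed_class == 3
        assert decision.fired_rule == "R1_benign_zone_downgrade"

    def test_damaging_ultrarare_retained(self):
        decision = reclassify(
            rule_input(
                original_class=4,
                zone=Zone.DAMAGING_MODY,
                band=FrequencyBand.MODY_COMPATIBLE,
                exon=5,
            )
        )
        assert decision.proposed_class == 4
        assert decision.fired_rule == "R5_retain_pathogenic"

    def test_liver_isoform_damaging_downgraded_stepwise(self):
        for original, proposed in [(4, 3), (3, 2), (2, 2)]:
            decision = reclassify(
                rule_input(original_class=original, zone=Zone.DAMAGING_MODY, exon=9)
            )
            assert decision.proposed_class == proposed

    def test_co_occurring_pathogenic_downgrade(self):
        decision = reclassify(
            rule_input(
                original_class=5,
                zone=Zone.DAMAGING_MODY,
                exon=3,
                co_occurring_pathogenic=True,
            )
        )
        assert decision.proposed_class == 3
        assert decision.fired_rule == "R3_co_occurrence_downgrade"

    def test_mixed_zone_abstains(self):
        decision = reclassify(rule_input(zone=Zone.MIXED))
        assert not decision.reviewed
        assert decision.proposed_class == decision.original_class

    def test_trace_lists_every_evaluated_rule(self):
        decision = reclassify(rule_input(original_class=2))
        assert len(decision.trace) == len(DEFAULT_RULES) + 1
        assert decision.trace[-1] == "default: retain"

    def test_deterministic(self):
        x = rule_input()
        assert reclassify(x) == reclassify(x)

    @given(
        original=st.integers(1, 5),
        zone=st.sampled_from(list(Zone)),
        band=st.sampled_from(list(FrequencyBand)),
        exon=st.integers(1, 10),
        co=st.booleans(),
    )
    def test_never_upgrades_toward_pathogenic(self, original, zone, band, exon, co):
        decision = reclassify(
            RuleInput("p.Test1Ala", original, zone, band, exon, co)
        )
        assert decision.proposed_class <= decision.original_class


class TestRegistryFixtures:
    def test_uk_overlap_reclassifies_exactly_the_seven_documented(self):
        decisions = reclassify_table(load_registry_fixture("UK"))
        changed = set(decisions.loc[decisions["changed"], "variant"])
        assert changed == {
            "p.Ala161Thr",
            "p.Ala174Val",
            "p.Gly606Ser",
            "p.His469Tyr",
            "p.Asn62Ser",
            "p.Pro291Ser",
            "p.Asp526Asn",
        }
        assert len(decisions) == 31

    def test_norway_overlap_five_changes_and_retained_pathogenic(self):
        decisions = reclassify_table(load_registry_fixture("NORWAY"))
        changed = set(decisions.loc[decisions["changed"], "variant"])
        assert changed == {
            "p.Tyr322Cys",
            "p.Thr354Met",
            "p.Thr441Lys",
            "p.Asp526Asn",
            "p.His582Arg",
        }
        retained = decisions[decisions["variant"] == "p.Ala276Asp"].iloc[0]
        assert retained["proposed_class"] == 4 and not retained["changed"]
        assert len(decisions) == 19


class TestRegistryReport:
    def test_published_registry_arithmetic(self):
        uk = registry_report(reclassify_table(load_registry_fixture("UK")), 162, "UK")
        assert (uk.pct_of_registry_rounded, uk.pct_of_overlap_rounded) == (4, 23)
        norway = registry_report(
            reclassify_table(load_registry_fixture("NORWAY")), 53, "NORWAY"
        )
        assert (norway.pct_of_registry_rounded, norway.pct_of_overlap_rounded) == (9, 26)

    def test_no_changes_gives_zero(self):
        decisions = pd.DataFrame({"changed": [False, False]})
        report = registry_report(decisions, 10)
        assert report.pct_of_registry == 0.0 and report.pct_of_overlap == 0.0

    def test_total_smaller_than_overlap_rejected(self):
        with pytest.raises(ValueError):
            registry_report(pd.DataFrame({"changed": [True, False]}), 1)
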