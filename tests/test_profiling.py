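"""Tests of strain profiling, proteome comparison and the trend statistic."""

import numpy as np
import pytest

from halocharge.catalog import roster_for
from halocharge.charge import ProteinSequence, classify_acidity, net_charge
from halocharge.halotolerance import HalotoleranceClass, SaltRange, StrainMetadata
from halocharge.profiling import (
    StrainProfile,
    always_basic_check,
    charge_table,
    compare_cluster_vs_proteome,
    profile_strain,
    render_profiles,
    trend_summary,
)


def _cluster_proteome(member_seqs: dict[str, str]) -> list[ProteinSequence]:
    """Annotated records for given universal-name -> sequence pairs."""
    roster = roster_for("Bacteria")
    records = []
    for member in roster.members:
        name = member.universal_name
        if name not in member_seqs:
            continue
        legacy = sorted(member.synonyms, key=len)[0]
        records.append(
            ProteinSequence(
                id=f"p_{name}",
                residues=member_seqs[name],
                annotation=f"50S ribosomal protein {legacy}",
            )
        )
    return records


NON_HALOPHILE_META = StrainMetadata(
    strain_id="nh1", domain="Bacteria",
    salt=SaltRange(optimal_low=0.0, optimal_high=1.0, tolerated_max=2.0,
                   grows_at_low_salt=True),
)
EXTREME_META = StrainMetadata(
    strain_id="ex1", domain="Bacteria",
    salt=SaltRange(required_min=20.0, optimal_low=20.0, optimal_high=25.0,
                   tolerated_max=30.0),
)

ROSTER_NAMES = roster_for("Bacteria").member_names


class TestProfileStrain:
    def test_basic_fixture_has_zero_acidic(self):
        proteome = _cluster_proteome({n: "KKKKKKKKKKKK" for n in ROSTER_NAMES})
        profile = profile_strain(proteome, NON_HALOPHILE_META)
        assert profile.n_found == 21
        assert profile.n_acidic == 0
        assert profile.halotolerance_class is HalotoleranceClass.NON_HALOPHILE

    def test_constructed_12_acidic_members_counted(self):
        seqs = {}
        for i, name in enumerate(ROSTER_NAMES):
            seqs[name] = "DDDDDDDDDDDD" if i < 12 else "KKKKKKKKKKKK"
        profile = profile_strain(_cluster_proteome(seqs), EXTREME_META)
        assert profile.n_acidic == 12
        assert profile.n_found == 21
        # the count is exactly the number of members labelled acidic
        labels = [c.acidity_label for c in profile.charges.values()]
        assert labels.count("acidic") == profile.n_acidic

    def test_missing_members_excluded_from_denominator(self):
        seqs = {n: "KKKKKKKK" for n in ROSTER_NAMES[:19]}
        profile = profile_strain(_cluster_proteome(seqs), NON_HALOPHILE_META)
        assert profile.n_found == 19
        assert set(profile.missing) == set(ROSTER_NAMES[19:])

    def test_n_acidic_non_increasing_as_cutoff_decreases(self):
        rng = np.random.default_rng(3)
        seqs = {
            n: "".join(rng.choice(list("KRDEAG"), size=40)) for n in ROSTER_NAMES
        }
        proteome = _cluster_proteome(seqs)
        counts = [
            profile_strain(proteome, NON_HALOPHILE_META, cutoff=c).n_acidic
            for c in (6.0, 3.0, 0.0, -3.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestProteomeComparison:
    def test_poly_aspartate_rest_fully_negative(self):
        cluster = _cluster_proteome({n: "KKKKKKKK" for n in ROSTER_NAMES})
        rest = [
            ProteinSequence(id=f"r{i}", residues="DDDDDDDD", annotation="hypothetical")
            for i in range(10)
        ]
        cmp = compare_cluster_vs_proteome(
            cluster + rest, {r.id for r in cluster}, strain_id="s"
        )
        assert cmp.rest_mean_charge < 0
        assert cmp.fraction_rest_negative == 1.0
        assert cmp.n_cluster == 21 and cmp.n_rest == 10

    def test_exchangeable_partitions_have_similar_means(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("KRDEAGST"), size=60)) for _ in range(300)]
        records = [
            ProteinSequence(id=f"r{i}", residues=s, annotation="x")
            for i, s in enumerate(seqs)
        ]
        cluster_ids = {f"r{i}" for i in range(0, 300, 2)}
        cmp = compare_cluster_vs_proteome(records, cluster_ids)
        spread = np.std([net_charge(r) for r in records])
        assert abs(cmp.cluster_mean_charge - cmp.rest_mean_charge) < spread / 2

    def test_empty_rest_partition_is_an_error(self):
        cluster = _cluster_proteome({n: "KKKK" for n in ROSTER_NAMES})
        with pytest.raises(ValueError, match="rest partition"):
            compare_cluster_vs_proteome(cluster, {r.id for r in cluster})


def _profile(strain_id, n_acidic, mean, klass, score, members=("uL2", "uS10")):
    """Hand-built profile with the stated acidic count and mean charge."""
    from halocharge.charge import ChargeResult

    charges = {}
    for i, m in enumerate(members):
        z = mean if i else mean  # every member at the mean keeps it simple
        charges[m] = ChargeResult(
            protein_id=f"{strain_id}_{m}", ph=7.4, scale_name="IPC_protein",
            net_charge=z, acidity_label=classify_acidity(z), length=100,
        )
    p = StrainProfile(
        strain_id=strain_id, domain="Bacteria", halotolerance_class=klass,
        charges=charges, n_found=len(members), n_acidic=n_acidic, missing=[],
        salt_score=score,
    )
    return p


class TestTrendSummary:
    def test_perfect_monotone_ranks(self):
        classes = list(HalotoleranceClass)
        profiles = [
            _profile(f"s{i}", n_acidic=i, mean=20.0 - 8 * i, klass=classes[i],
                     score=2.0 + 7 * i)
            for i in range(5)
        ]
        report = trend_summary(profiles, n_permutations=2000, seed=0)
        assert report.rho_n_acidic == pytest.approx(1.0)
        assert report.rho_mean_charge == pytest.approx(-1.0)
        assert not report.degenerate

    def test_shuffled_labels_not_significant(self):
        rng = np.random.default_rng(12)
        scores = rng.permutation(20).astype(float)
        means = rng.normal(size=20) * 5
        classes = [
            HalotoleranceClass.NON_HALOPHILE if i < 10 else HalotoleranceClass.EXTREME_HALOPHILE
            for i in range(20)
        ]
        profiles = [
            _profile(f"s{i}", n_acidic=int(rng.integers(0, 21)), mean=means[i],
                     klass=classes[i], score=scores[i])
            for i in range(20)
        ]
        report = trend_summary(profiles, seed=3)
        assert abs(report.rho_mean_charge) < 0.5
        assert report.p_mean_charge > 0.05

    def test_invariant_to_strain_order_and_monotone_reencoding(self):
        classes = list(HalotoleranceClass)
        profiles = [
            _profile(f"s{i}", n_acidic=i, mean=10.0 - 3 * i, klass=classes[i % 5],
                     score=float(i))
            for i in range(8)
        ]
        base = trend_summary(profiles, n_permutations=1000, seed=0)
        reordered = trend_summary(profiles[::-1], n_permutations=1000, seed=0)
        assert base.rho_mean_charge == pytest.approx(reordered.rho_mean_charge)
        # monotone re-encoding of the salt axis: x -> exp(x)
        for p in profiles:
            p.salt_score = float(np.exp(p.salt_score / 4.0))
        recoded = trend_summary(profiles, n_permutations=1000, seed=0)
        assert base.rho_mean_charge == pytest.approx(recoded.rho_mean_charge)

    def test_degenerate_constant_input_reported_not_crashed(self):
        classes = [
            HalotoleranceClass.NON_HALOPHILE,
            HalotoleranceClass.EXTREME_HALOPHILE,
            HalotoleranceClass.EXTREME_HALOPHILE,
        ]
        profiles = [
            _profile(f"s{i}", n_acidic=3, mean=5.0, klass=classes[i], score=4.0)
            for i in range(3)
        ]
        report = trend_summary(profiles, n_permutations=100, seed=0)
        assert report.degenerate
        assert np.isnan(report.rho_mean_charge)

    def test_too_few_strains_or_classes_rejected(self):
        p = _profile("s", 0, 5.0, HalotoleranceClass.NON_HALOPHILE, 1.0)
        with pytest.raises(ValueError, match="at least 3"):
            trend_summary([p, p])
        with pytest.raises(ValueError, match="2 classes"):
            trend_summary([p, p, p])


class TestAlwaysBasic:
    def test_single_member_surviving_everywhere(self):
        profiles = []
        for i in range(4):
            members = {"uL2": 8.0, "uS10": 6.0 if i != 2 else 1.0}
            charges = {}
            from halocharge.charge import ChargeResult

            for m, z in members.items():
                charges[m] = ChargeResult(f"p{i}_{m}", 7.4, "IPC_protein", z,
                                          classify_acidity(z), 90)
            profiles.append(
                StrainProfile(f"s{i}", "Bacteria", None, charges, 2,
                              sum(1 for z in members.values() if z < 3), [])
            )
        assert always_basic_check(profiles) == ["uL2"]

    def test_single_all_basic_profile_returns_full_roster(self):
        proteome = _cluster_proteome({n: "KKKKKKKK" for n in ROSTER_NAMES})
        profile = profile_strain(proteome, NON_HALOPHILE_META)
        assert set(always_basic_check([profile])) == set(ROSTER_NAMES)

    def test_borderline_member_excluded(self):
        from halocharge.charge import ChargeResult

        charges = {"uL2": ChargeResult("p_uL2", 7.4, "IPC_protein", 2.9, "acidic", 90)}
        profile = StrainProfile("s", "Bacteria", None, charges, 1, 1, [])
        assert always_basic_check([profile]) == []

    def test_adding_profiles_only_shrinks_the_set(self, synthetic_study):
        _, profiles = synthetic_study
        subset = always_basic_check(profiles[:3])
        full = always_basic_check(profiles)
        assert set(full) <= set(subset)


class TestRendering:
    def test_files_created_and_colors_match_classifier(self, synthetic_study, tmp_path):
        _, profiles = synthetic_study
        chosen = profiles[:3]
        paths = render_profiles(chosen, tmp_path)
        assert len(paths) == 1 + 3
        assert all(p.exists() and p.stat().st_size > 0 for p in paths)
        # pixel-free structural check: the plotted table reproduces the labels
        table = charge_table(chosen)
        for profile in chosen:
            for member, result in profile.charges.items():
                cell = table.loc[profile.strain_id, member]
                assert classify_acidity(cell) == result.acidity_label

    def test_missing_members_render_as_gaps_not_zero(self, tmp_path):
        seqs = {n: "KKKKKKKK" for n in ROSTER_NAMES[:15]}
        profile = profile_strain(_cluster_proteome(seqs), NON_HALOPHILE_META)
        table = charge_table([profile])
        missing_cells = table.loc[profile.strain_id, profile.missing]
        assert missing_cells.isna().all()
        render_profiles([profile], tmp_path)  # must not crash on gaps
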