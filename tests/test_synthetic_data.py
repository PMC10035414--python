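import hashlib

import numpy as np
import pandas as pd
import pytest

from famscan import expression_screen as es
from famscan.domain_conservation import E_BOX, G_BOX, NON_E_BOX, classify_binding
from famscan.errors import ConfigurationError
from famscan.family_identification import MODEL_LENGTH
from famscan.qpcr_stats import relative_expression_ddct
from famscan.synthetic_data import (
    CLUSTER_SHAPES,
    ClusterSpec,
    ExpressionDesign,
    FixturePreset,
    NOISE_FREE,
    QpcrDesign,
    make_fixture,
    preset_cp159,
    preset_tiny,
    synth_domain_row,
    synth_domain_sequence,
    synth_expression,
    synth_qpcr,
)


def _hash_dir(path):
    return {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(path.iterdir())
    }


class TestPresets:
    def test_cp159_composition(self):
        p = preset_cp159()
        p.validate()
        assert p.n_putative == 174
        assert p.n_valid == 159
        assert p.n_chromosomes == 21
        assert sum(p.binding_composition.values()) == 159
        assert p.exon_distribution[1] == 20
        assert max(p.exon_distribution) == 13
        assert p.n_unexpressed == 19  # 4 planted members + 15 decoy rows

    def test_inconsistent_composition_rejected(self):
        p = preset_tiny(n_valid=4)
        bad = FixturePreset(
            **{
                **{f: getattr(p, f) for f in p.__dataclass_fields__},
                "binding_composition": {G_BOX: 3},  # sums to n_valid - 1
            }
        )
        with pytest.raises(ConfigurationError, match="binding composition"):
            make_fixture(bad, seed=1)

    def test_bad_exon_distribution_rejected(self):
        p = preset_tiny(n_valid=4)
        bad = FixturePreset(
            **{
                **{f: getattr(p, f) for f in p.__dataclass_fields__},
                "exon_distribution": {1: 2},
            }
        )
        with pytest.raises(ConfigurationError, match="exon distribution"):
            bad.validate()


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        preset = preset_tiny(n_valid=3, n_chromosomes=1, n_duplicate_decoys=0)
        make_fixture(preset, seed=7).write(tmp_path / "a")
        make_fixture(preset, seed=7).write(tmp_path / "b")
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        preset = preset_tiny(n_valid=3, n_chromosomes=1)
        make_fixture(preset, seed=1).write(tmp_path / "a")
        make_fixture(preset, seed=2).write(tmp_path / "b")
        assert _hash_dir(tmp_path / "a") != _hash_dir(tmp_path / "b")


class TestBundleInvariants:
    def test_every_gene_has_all_artifacts(self, cp159_bundle):
        b = cp159_bundle
        gene_ids = set(b.gene_models)
        assert len(gene_ids) == 174
        assert gene_ids == {p.id for p in b.proteins}
        assert gene_ids == set(b.promoters)
        assert gene_ids == set(b.expression.index)
        assert gene_ids == set(b.truth)

    def test_domain_rows_are_model_length(self, cp159_bundle):
        for t in cp159_bundle.truth.values():
            assert len(t.domain_row) == MODEL_LENGTH
            assert t.exon_count >= 1

    def test_truth_binding_consistent_with_rows(self, cp159_bundle):
        for t in cp159_bundle.truth.values():
            if t.kind != "truncated":
                assert classify_binding(t.domain_row).klass == t.binding_class

    def test_cp159_truth_census(self, cp159_bundle):
        members = [t for t in cp159_bundle.truth.values() if t.is_family_member]
        assert len(members) == 159
        census = {}
        for t in members:
            census[t.binding_class] = census.get(t.binding_class, 0) + 1
        assert census == {G_BOX: 93, E_BOX: 43, NON_E_BOX: 23}

    def test_cp159_chromosomes_and_exons(self, cp159_bundle):
        members = [t for t in cp159_bundle.truth.values() if t.is_family_member]
        chroms = {
            cp159_bundle.gene_models[t.gene_id].chromosome for t in members
        }
        assert len(chroms) == 21
        counts = [t.exon_count for t in members]
        assert sum(1 for c in counts if c == 1) == 20
        assert sum(1 for c in counts if c == 2) == 13
        assert min(counts) == 1 and max(counts) == 13

    def test_member_names_follow_chromosomal_order(self, cp159_bundle):
        members = sorted(
            (t for t in cp159_bundle.truth.values() if t.is_family_member),
            key=lambda t: t.member_rank,
        )
        assert [t.member_rank for t in members] == list(range(1, 160))
        assert members[0].member_name == "CpbHLH1"
        assert members[-1].member_name == "CpbHLH159"


class TestSynthDomain:
    @pytest.mark.parametrize("klass", [G_BOX, E_BOX, NON_E_BOX])
    def test_classify_round_trip_1000(self, klass):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            row = synth_domain_row(klass, rng)
            assert classify_binding(row).klass == klass

    def test_gbox_residues(self):
        rng = np.random.default_rng(0)
        row = synth_domain_row(G_BOX, rng)
        assert row[12] == "E" and row[15] == "R" and row[16] == "R"
        assert row[8] in "HK"

    def test_non_ebox_breaks_core(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            row = synth_domain_row(NON_E_BOX, rng)
            assert not (row[12] == "E" and row[15] == "R")

    def test_sequence_contains_planted_domain(self):
        rng = np.random.default_rng(3)
        seq, start, row = synth_domain_sequence(G_BOX, rng, noise=NOISE_FREE)
        assert seq[start : start + MODEL_LENGTH] == row


class TestSynthExpression:
    def _design(self, profile, n=1, noise=0.1, unexpressed=0):
        return ExpressionDesign(
            treatments=("CK", "LS", "MS", "HS"),
            clusters=(ClusterSpec("A1", profile, n),),
            noise_sd=noise,
            unexpressed=unexpressed,
        )

    def test_constant_cluster_zero_fold_change(self):
        rng = np.random.default_rng(0)
        lfc = []
        for _ in range(200):
            frame, _, _ = synth_expression(
                self._design((0.0, 0.0, 0.0, 0.0)), rng
            )
            row = frame.iloc[0]
            lfc.append(np.log2(row[["LS", "MS", "HS"]] / row["CK"]))
        assert np.allclose(np.mean(lfc, axis=0), 0.0, atol=0.05)

    def test_planted_threefold_recovered_within_20pct(self):
        rng = np.random.default_rng(1)
        profile = (0.0, -np.log2(3.0), 0.0, 0.0)
        ratios = []
        for _ in range(200):
            frame, _, folds = synth_expression(self._design(profile), rng)
            gene = frame.index[0]
            assert folds[gene]["LS"] == pytest.approx(1 / 3)
            row = frame.iloc[0]
            ratios.append(row["CK"] / row["LS"])
        est = 2.0 ** np.mean(np.log2(ratios))
        assert abs(est - 3.0) / 3.0 < 0.2

    def test_unexpressed_below_filter(self):
        rng = np.random.default_rng(2)
        frame, _, _ = synth_expression(
            self._design((0.0,) * 4, n=2, unexpressed=3), rng
        )
        retained, _ = es.filter_and_normalize(frame, 1.0)
        assert len(retained) == 2

    def test_cp159_unexpressed_count_matches_preset(self, cp159_bundle):
        preset = cp159_bundle.preset
        retained, _ = es.filter_and_normalize(cp159_bundle.expression, 1.0)
        n_failing = len(cp159_bundle.expression) - len(retained)
        assert n_failing == preset.n_unexpressed
        assert len(retained) == 155


class TestSynthQpcr:
    def test_flat_ratios_noise_free(self):
        design = QpcrDesign(ratios={"g1": {"CK": 1.0, "T1": 1.0, "T2": 1.0}})
        table = synth_qpcr(design, np.random.default_rng(0))
        detail, _ = relative_expression_ddct(table, "18sRNA", "CK")
        assert np.allclose(detail["rel_expr"], 1.0)

    def test_half_ratio_noise_free(self):
        design = QpcrDesign(ratios={"g1": {"CK": 1.0, "T1": 0.5, "T2": 1.0}})
        table = synth_qpcr(design, np.random.default_rng(0))
        detail, _ = relative_expression_ddct(table, "18sRNA", "CK")
        t1 = detail[detail["treatment"] == "T1"]["rel_expr"]
        assert np.allclose(t1, 0.5)

    def test_reference_rows_for_every_sample(self):
        design = QpcrDesign(
            ratios={"g1": {"CK": 1.0, "T1": 2.0}}, noise_sd=0.3
        )
        table = synth_qpcr(design, np.random.default_rng(4))
        ref = table[table["gene"] == "18sRNA"]
        assert set(zip(ref["treatment"], ref["bio_rep"])) >= {
            (t, b) for t in design.treatments for b in (1, 2, 3)
        }

    def test_monte_carlo_ratio_recovery(self):
        rng = np.random.default_rng(6)
        design = QpcrDesign(
            ratios={"g1": {"CK": 1.0, "T1": 2.0, "T2": 1.0}}, noise_sd=0.2
        )
        recovered = []
        for _ in range(500):
            table = synth_qpcr(design, rng)
            detail, _ = relative_expression_ddct(table, "18sRNA", "CK")
            t1 = detail[detail["treatment"] == "T1"]["rel_expr"]
            recovered.append(t1.mean())
        assert abs(np.mean(recovered) - 2.0) / 2.0 < 0.15
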