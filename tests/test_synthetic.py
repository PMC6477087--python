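"""Synthetic cohort generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from lncscope import io as lio
from lncscope.diffexpr import call_de
from lncscope.synthetic import (
    CisPair,
    SimConfig,
    TransBlock,
    generate_cohort,
    generate_interaction_table,
    write_fixture,
)


def _pair_config(r, n_tumor, n_control, seed=0, noise_sd=0.5):
    return SimConfig(
        n_tumor=n_tumor,
        n_control=n_control,
        n_mrna=1,
        n_lncrna=1,
        cis_pairs=(CisPair("LNC0001", "MRNA0001", 1000, r),),
        noise_sd=noise_sd,
        seed=seed,
    )


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_mrna=20, n_lncrna=5, seed=11)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)

    def test_different_seed_differs(self):
        a = generate_cohort(SimConfig(n_mrna=5, n_lncrna=2, seed=1))
        b = generate_cohort(SimConfig(n_mrna=5, n_lncrna=2, seed=2))
        assert not a.expression.values.equals(b.expression.values)

    def test_adding_genes_leaves_existing_noise_unchanged(self):
        a = generate_cohort(SimConfig(n_mrna=5, n_lncrna=2, seed=3))
        b = generate_cohort(SimConfig(n_mrna=9, n_lncrna=2, seed=3))
        shared = a.expression.values.index[:5]
        pd.testing.assert_frame_equal(
            a.expression.values.loc[shared], b.expression.values.loc[shared]
        )


class TestDegenerateAndValidation:
    def test_zero_noise_no_effects_constant_genes(self):
        cfg = SimConfig(n_mrna=3, n_lncrna=2, noise_sd=0.0, seed=0)
        cohort = generate_cohort(cfg)
        assert (cohort.expression.values.nunique(axis=1) == 1).all()

    def test_invalid_configs_name_offending_field(self):
        with pytest.raises(ValueError, match="n_tumor"):
            generate_cohort(SimConfig(n_tumor=1))
        with pytest.raises(ValueError, match="n_control"):
            generate_cohort(SimConfig(n_control=1))
        with pytest.raises(ValueError, match="planted_de"):
            generate_cohort(SimConfig(planted_de=(("NOPE", 1.0),)))
        with pytest.raises(ValueError, match="gap"):
            generate_cohort(
                SimConfig(cis_pairs=(CisPair("LNC0001", "MRNA0001", -5, 0.5),))
            )
        with pytest.raises(ValueError, match="r out of"):
            generate_cohort(
                SimConfig(cis_pairs=(CisPair("LNC0001", "MRNA0001", 5, 1.0),))
            )

    def test_expression_shape_and_nonnegativity(self):
        cfg = SimConfig(n_mrna=8, n_lncrna=4, seed=5)
        cohort = generate_cohort(cfg)
        assert cohort.expression.values.shape == (12, 10)
        assert (cohort.expression.values.to_numpy() >= 0).all()


class TestPlantedCorrelation:
    def test_pair_r_near_target_at_n50(self):
        # sampling sd of r at n=50, rho=0.9 is ~(1-rho^2)/sqrt(n) ~ 0.03
        cohort = generate_cohort(_pair_config(0.9, 25, 25, seed=42))
        log = cohort.expression.log2p1()
        r = np.corrcoef(log.loc["LNC0001"], log.loc["MRNA0001"])[0, 1]
        assert r == pytest.approx(0.9, abs=0.1)

    def test_negative_target_r(self):
        cohort = generate_cohort(_pair_config(-0.8, 25, 25, seed=42))
        log = cohort.expression.log2p1()
        r = np.corrcoef(log.loc["LNC0001"], log.loc["MRNA0001"])[0, 1]
        assert r == pytest.approx(-0.8, abs=0.12)

    @pytest.mark.parametrize("target", [0.3, 0.6, 0.9])
    def test_mean_r_calibrated_over_replicates(self, target):
        # 200 replicate cohorts at n=20: the mean sample r must sit within
        # +/-0.05 of the configured target
        rs = []
        for rep in range(200):
            cohort = generate_cohort(_pair_config(target, 10, 10, seed=rep))
            log = cohort.expression.log2p1()
            rs.append(np.corrcoef(log.loc["LNC0001"], log.loc["MRNA0001"])[0, 1])
        assert np.mean(rs) == pytest.approx(target, abs=0.05)


class TestPlantedDE:
    def test_mean_observed_log2fc_tracks_effect(self):
        effect = 2.0
        fcs = []
        for rep in range(40):
            cfg = SimConfig(
                n_mrna=4, n_lncrna=1,
                planted_de=(("MRNA0001", effect),), seed=1000 + rep,
            )
            cohort = generate_cohort(cfg)
            de = call_de(cohort.expression).set_index("gene_id")
            fcs.append(de.at["MRNA0001", "log2fc"])
        assert np.mean(fcs) == pytest.approx(effect, abs=0.2)


class TestInteractionTable:
    def test_true_targets_span_retention_threshold(self):
        cfg = SimConfig(n_mrna=20, n_lncrna=6, seed=1)
        targets = [("LNC0001", f"MRNA{i:04d}") for i in range(1, 13)]
        table = generate_interaction_table(cfg, targets)
        assert len(table) == 12
        assert (table["sumenergy"] > 2000).all()
        assert (table["sumenergy"] <= 4000).all()

    def test_background_scores_below_substrate_cut(self):
        cfg = SimConfig(n_mrna=20, n_lncrna=6, seed=1)
        table = generate_interaction_table(cfg, [], n_background=30)
        assert len(table) == 30
        assert (table["sumenergy"] <= 1500).all()
        assert (table["sumenergy"] > 0).all()

    def test_promiscuous_mrna_has_five_strong_hosts(self):
        cfg = SimConfig(n_mrna=20, n_lncrna=6, seed=1)
        table = generate_interaction_table(cfg, [], n_promiscuous=1)
        hosts = table.groupby("mrna_id")["lncrna_id"].nunique()
        assert (hosts == 5).all()
        assert (table["sumenergy"] > 1500).all()

    def test_empty_truth_and_background(self):
        cfg = SimConfig(n_mrna=5, n_lncrna=5, seed=1)
        assert generate_interaction_table(cfg, []).empty

    def test_too_many_promiscuous_errors(self):
        cfg = SimConfig(n_mrna=3, n_lncrna=6, seed=1)
        with pytest.raises(ValueError, match="n_promiscuous"):
            generate_interaction_table(cfg, [], n_promiscuous=10)


class TestFixtureRoundTrip:
    def test_manifest_and_lossless_round_trip(self, tmp_path):
        cfg = SimConfig(
            n_mrna=6, n_lncrna=3, seed=9,
            cis_pairs=(CisPair("LNC0001", "MRNA0001", 250, 0.5),),
        )
        cohort = generate_cohort(cfg)
        cohort.interactions = generate_interaction_table(
            cfg, [("LNC0002", "MRNA0002")], n_background=3
        )
        manifest = write_fixture(cohort, tmp_path)
        assert len(manifest) == 4

        back = lio.read_gtf(manifest["annotation"])
        orig = {(g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype)
                for g in cohort.annotation}
        got = {(g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype)
               for g in back}
        assert got == orig

        expr = lio.read_expression(manifest["expression"], manifest["samples"])
        pd.testing.assert_frame_equal(
            expr.values, cohort.expression.values,
            check_exact=False, rtol=1e-5, check_names=False,
        )
        inter = lio.read_interactions(manifest["interactions"])
        assert len(inter) == len(cohort.interactions)
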