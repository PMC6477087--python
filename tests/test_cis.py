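"""Genomic-distance classification and lncRNA/neighbor pairing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lncscope import cis as cis_mod
from lncscope.types import GeneAnnotation


def _gene(gid, start, end, chrom="chr1", biotype="coding"):
    return GeneAnnotation(gid, chrom, start, end, "+", biotype)


class TestIntervalGap:
    def test_overlapping_intervals_gap_zero(self):
        assert cis_mod.interval_gap(_gene("a", 1000, 2000), _gene("b", 1500, 3000)) == 0

    def test_disjoint_gap_is_boundary_distance(self):
        assert cis_mod.interval_gap(_gene("a", 1000, 2000), _gene("b", 7000, 8000)) == 5000

    def test_different_chromosomes_infinite(self):
        a, b = _gene("a", 0, 10), _gene("b", 0, 10, chrom="chr2")
        assert cis_mod.interval_gap(a, b) == math.inf

    @given(
        st.integers(0, 10**6), st.integers(1, 10**4),
        st.integers(0, 10**6), st.integers(1, 10**4),
    )
    def test_symmetry(self, s1, l1, s2, l2):
        a, b = _gene("a", s1, s1 + l1), _gene("b", s2, s2 + l2)
        assert cis_mod.interval_gap(a, b) == cis_mod.interval_gap(b, a)


class TestClassBoundaries:
    @pytest.mark.parametrize(
        "gap,expected",
        [
            (0, "overlap"),
            (1, "adjoining"),
            (5000, "adjoining"),
            (5001, "proximal"),
            (10000, "proximal"),
            (10001, "others"),
            (math.inf, "others"),
        ],
    )
    def test_partition_at_stated_boundaries(self, gap, expected):
        assert cis_mod.classify_gap(gap) == expected

    @given(st.integers(0, 50_000))
    def test_every_gap_maps_to_exactly_one_class(self, gap):
        classes = [
            c for c in cis_mod.DISTANCE_CLASSES if cis_mod.classify_gap(gap) == c
        ]
        assert len(classes) == 1


class TestClassifyLnc:
    def test_nearest_neighbor_and_class(self):
        genes = [
            _gene("M1", 0, 1000),
            _gene("M2", 11_000, 12_000),
            _gene("L1", 1_500, 2_000, biotype="lncRNA"),
        ]
        cls, nearest, gap = cis_mod.classify_lnc(genes[2], genes)
        assert (cls, nearest, gap) == ("adjoining", "M1", 500)

    def test_no_same_chromosome_gene(self):
        lnc = _gene("L1", 0, 100, biotype="lncRNA")
        other = _gene("M1", 0, 100, chrom="chr9")
        cls, nearest, gap = cis_mod.classify_lnc(lnc, [lnc, other])
        assert cls == "others" and gap == math.inf

    def test_vectorized_classification_matches_brute_force(self, rng):
        # 200-gene synthetic chromosome; oracle = all-pairs python scan
        genes = []
        pos = 0
        for i in range(200):
            length = int(rng.integers(500, 3000))
            genes.append(
                _gene(
                    f"G{i:03d}", pos, pos + length,
                    biotype="lncRNA" if i % 4 == 0 else "coding",
                )
            )
            pos += length + int(rng.integers(0, 15_000))
        lncs = [g for g in genes if g.biotype == "lncRNA"]
        table = cis_mod.classify_all(lncs, genes).set_index("lncrna_id")
        for lnc in lncs:
            cls, nearest, gap = cis_mod.classify_lnc(lnc, genes)
            assert table.at[lnc.gene_id, "distance_class"] == cls
            assert table.at[lnc.gene_id, "gap_bp"] == gap
            assert table.at[lnc.gene_id, "nearest_id"] == nearest


def _de_row(gid, biotype, fc, p=0.001):
    sig = abs(fc) > 1 and p < 0.05
    return {
        "gene_id": gid, "biotype": biotype, "log2fc": fc, "p_value": p,
        "q_value": p, "significant": sig,
        "direction": ("up" if fc > 0 else "down") if sig else "none",
    }


class TestPairing:
    def test_overlap_concordant_down_down(self):
        # lncRNA and its host gene both reduced: the overlapping
        # concordant pattern
        genes = [
            _gene("GNB5L", 1000, 5000),
            _gene("CERNA1L", 2000, 3000, biotype="lncRNA"),
        ]
        de = pd.DataFrame(
            [_de_row("GNB5L", "coding", -2.0), _de_row("CERNA1L", "lncRNA", -2.5)]
        )
        pairs = cis_mod.pair_with_de_neighbors(de, genes)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["distance_class"] == "overlap"
        assert row["concordance"] == "concordant"

    def test_adjoining_anticorrelated_down_up(self):
        # lncRNA down, neighbor 2 kb away up: anti-correlated adjoining pair
        genes = [
            _gene("NUP50L", 10_000, 12_000),
            _gene("NUP50ASL", 14_000, 15_000, biotype="lncRNA"),
        ]
        de = pd.DataFrame(
            [_de_row("NUP50L", "coding", 1.8), _de_row("NUP50ASL", "lncRNA", -2.0)]
        )
        pairs = cis_mod.pair_with_de_neighbors(de, genes)
        row = pairs.iloc[0]
        assert row["distance_class"] == "adjoining"
        assert row["gap_bp"] == 2000
        assert row["concordance"] == "anti-correlated"

    def test_planted_gap_ladder_classes_and_exclusion(self):
        # neighbors at gaps spanning every bin; the >10 kb pair must not
        # be emitted
        gaps = [0, 100, 4999, 5001, 9999, 10050]
        genes, de_rows = [], []
        for i, gap in enumerate(gaps):
            base = i * 1_000_000
            mrna = _gene(f"M{i}", base, base + 2000)
            if gap == 0:
                lnc = _gene(f"L{i}", base + 500, base + 1500, biotype="lncRNA")
            else:
                lnc = _gene(
                    f"L{i}", base + 2000 + gap, base + 3000 + gap, biotype="lncRNA"
                )
            genes += [mrna, lnc]
            de_rows += [
                _de_row(f"M{i}", "coding", 2.0),
                _de_row(f"L{i}", "lncRNA", 2.0),
            ]
        pairs = cis_mod.pair_with_de_neighbors(pd.DataFrame(de_rows), genes)
        got = dict(zip(pairs["lncrna_id"], pairs["distance_class"]))
        assert got == {
            "L0": "overlap",
            "L1": "adjoining",
            "L2": "adjoining",
            "L3": "proximal",
            "L4": "proximal",
        }
        assert "L5" not in set(pairs["lncrna_id"])

    def test_nearest_neighbor_flagged_primary(self):
        genes = [
            _gene("M_near", 10_000, 11_000),
            _gene("M_far", 20_000, 21_000),
            _gene("L1", 12_000, 13_000, biotype="lncRNA"),
        ]
        de = pd.DataFrame(
            [
                _de_row("M_near", "coding", 2.0),
                _de_row("M_far", "coding", 2.0),
                _de_row("L1", "lncRNA", 2.0),
            ]
        )
        pairs = cis_mod.pair_with_de_neighbors(de, genes).set_index("neighbor_id")
        assert bool(pairs.at["M_near", "primary"])
        assert not bool(pairs.at["M_far", "primary"])

    def test_nonsignificant_neighbors_ignored(self):
        genes = [
            _gene("M1", 10_000, 11_000),
            _gene("L1", 12_000, 13_000, biotype="lncRNA"),
        ]
        de = pd.DataFrame(
            [_de_row("M1", "coding", 0.2, p=0.9), _de_row("L1", "lncRNA", 2.0)]
        )
        assert cis_mod.pair_with_de_neighbors(de, genes).empty
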