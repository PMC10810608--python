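"""Repertoire statistics: filters, usage tables, correlations, clonotypes."""

import numpy as np
import pandas as pd
import pytest

from bcrep import (
    cdr3_properties,
    clonotype_table,
    editing_signature,
    gene_usage,
    isotype_family_frequencies,
    pearson_usage,
    preprocess,
    productivity_fractions,
    vj_pairing_matrix,
)
from bcrep.stats import UsageTable


def _rec(
    locus="IGK",
    cdr3="ARDY",
    productive=True,
    failure="none",
    v="Igkv1",
    j="Igkj1",
    cell="c0",
    dup=1,
):
    junction = "C" + cdr3 + "F" if productive else ""
    return {
        "sequence_id": f"{cell}|light",
        "cell_id": cell,
        "locus": locus if failure != "non_ig" else "",
        "v_call": v,
        "d_call": "",
        "j_call": j,
        "junction": "",
        "junction_aa": junction,
        "cdr3_aa": cdr3 if productive else "",
        "productive": productive,
        "failure_mode": failure,
        "v_score": 100.0,
        "j_score": 50.0,
        "duplicate_count": dup,
    }


def _table(rows):
    return pd.DataFrame(rows)


class TestPreprocess:
    def test_removes_unproductive_and_singletons(self):
        df = _table(
            [
                _rec(cdr3="AAAA", cell="c1"),
                _rec(cdr3="AAAA", cell="c2"),
                _rec(cdr3="CCCC", cell="c3"),  # singleton
                _rec(cdr3="", productive=False, failure="stop_codon", cell="c4"),
            ]
        )
        out = preprocess(df, min_cdr3_aa_len=4, min_occurrence=2)
        assert set(out["cdr3_aa"]) == {"AAAA"}
        assert len(out) == 2

    def test_length_filter(self):
        df = _table([_rec(cdr3="AAA"), _rec(cdr3="AAAA")])
        out = preprocess(df, min_cdr3_aa_len=4, min_occurrence=1)
        assert set(out["cdr3_aa"]) == {"AAAA"}

    def test_identity_on_productive_subset(self):
        df = _table([_rec(cdr3="A"), _rec(productive=False, failure="out_of_frame")])
        out = preprocess(df, min_cdr3_aa_len=0, min_occurrence=1)
        assert len(out) == 1
        assert out["productive"].all()

    def test_idempotent(self, ctrl_small):
        _, _, _, annotations = ctrl_small
        once = preprocess(annotations)
        twice = preprocess(once)
        assert once.equals(twice)


class TestUsage:
    def test_usage_table_is_distribution(self, ctrl_small, germline):
        _, _, _, annotations = ctrl_small
        for locus in ("IGH", "IGK"):
            for axis in ("v_gene", "j_gene"):
                t = gene_usage(annotations, axis, locus, germline)
                assert abs(t.frequencies.sum() - 1.0) < 1e-9
                assert (t.counts >= 0).all()

    def test_single_record(self):
        df = _table([_rec(v="Igkv3")])
        t = gene_usage(df, "v_gene", "IGK")
        assert t["Igkv3"] == 1.0

    def test_uniform_igkv_multinomial(self, germline):
        """Uniform V draws at n=15000: each of 15 genes at 1/15 +/- 3 SE."""
        import bcrep

        rng = np.random.default_rng(21)
        preset = bcrep.get_preset("ctrl")
        draws = [
            bcrep.rearrange_light_empirical(germline, preset, rng)
            for _ in range(15000)
        ]
        rows = [
            _rec(v=r.v_name, j=r.j_name, cell=f"c{i}")
            for i, r in enumerate(draws)
            if r.locus == "IGK" and r.is_productive_truth
        ]
        t = gene_usage(_table(rows), "v_gene", "IGK", germline)
        p = 1 / 15
        se = np.sqrt(p * (1 - p) / t.total)
        assert np.all(np.abs(t.frequencies - p) <= 3 * se)


class TestPearson:
    def test_self_correlation(self):
        t = UsageTable("j_gene", "IGK", ["a", "b", "c"], np.array([5, 3, 2]))
        r, p = pearson_usage(t, t)
        assert r == pytest.approx(1.0)

    def test_symmetric_reversal(self):
        # closed form for (0.5,0.3,0.2) vs its reversal: r = -13/14
        a = UsageTable("j_gene", None, ["a", "b", "c"], np.array([5, 3, 2]))
        b = UsageTable("j_gene", None, ["a", "b", "c"], np.array([2, 3, 5]))
        r, _ = pearson_usage(a, b)
        assert r == pytest.approx(-13 / 14)
        # a strictly affine decreasing pair does reach -1
        c = UsageTable("j_gene", None, ["a", "b", "c"], np.array([1, 3, 6]))
        d = UsageTable("j_gene", None, ["a", "b", "c"], np.array([6, 4, 1]))
        r2, _ = pearson_usage(c, d)
        assert r2 == pytest.approx(-1.0)

    def test_symmetry_and_relabel_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, size=6)
        other = rng.integers(1, 50, size=6)
        labels = list("abcdef")
        a = UsageTable("v_gene", None, labels, counts)
        b = UsageTable("v_gene", None, labels, other)
        r_ab, _ = pearson_usage(a, b)
        r_ba, _ = pearson_usage(b, a)
        assert r_ab == pytest.approx(r_ba)
        perm = ["f", "a", "c", "b", "e", "d"]
        idx = [labels.index(l) for l in perm]
        ap = UsageTable("v_gene", None, perm, counts[idx])
        bp = UsageTable("v_gene", None, perm, other[idx])
        r_p, _ = pearson_usage(ap, bp)
        assert r_p == pytest.approx(r_ab)

    def test_too_few_labels(self):
        t = UsageTable("j_gene", None, ["a", "b"], np.array([1, 1]))
        with pytest.raises(ValueError):
            pearson_usage(t, t)

    def test_replicate_samples_correlate(self, germline):
        """Two independent draws of one preset: r > 0.95 at n=10000."""
        import bcrep

        tables = []
        preset = bcrep.get_preset("ctrl")
        for seed in (31, 32):
            rng = np.random.default_rng(seed)
            rows = [
                _rec(v=r.v_name, j=r.j_name, cell=f"c{i}")
                for i, r in enumerate(
                    bcrep.rearrange_light_empirical(germline, preset, rng)
                    for _ in range(10000)
                )
                if r.locus == "IGK" and r.is_productive_truth
            ]
            tables.append(gene_usage(_table(rows), "j_gene", "IGK", germline))
        r, _ = pearson_usage(*tables)
        assert r > 0.95


class TestPairingAndEditing:
    def test_hand_built_matrix(self, germline):
        rows = [
            _rec(locus="IGL", v="Iglv1", j="Iglj1", cell=f"c{i}") for i in range(3)
        ] + [
            _rec(locus="IGL", v="Iglv2", j="Iglj2", cell="c3"),
            _rec(locus="IGL", v="Iglv3", j="Iglj2", cell="c4"),
            _rec(locus="IGL", v="Iglv1", j="Iglj3", cell="c5"),
        ]
        counts, freq, cross = vj_pairing_matrix(_table(rows), "IGL", germline)
        assert counts.loc["Iglv1", "Iglj1"] == 3
        assert counts.loc["Iglv2", "Iglj2"] == 1
        assert counts.to_numpy().sum() == 6
        assert cross == 0.0
        assert freq.loc["Iglv1", "Iglj1"] == pytest.approx(0.75)

    def test_cross_cassette_mass_detects_violation(self, germline):
        rows = [
            _rec(locus="IGL", v="Iglv1", j="Iglj1", cell="c0"),
            _rec(locus="IGL", v="Iglv2", j="Iglj1", cell="c1"),  # cross
        ]
        _, _, cross = vj_pairing_matrix(_table(rows), "IGL", germline)
        assert cross == pytest.approx(0.5)

    def test_editing_signature(self):
        rows = [_rec(j="Igkj1", cell=f"a{i}") for i in range(9)] + [
            _rec(j="Igkj5", cell="b0")
        ]
        table, jk5 = editing_signature(_table(rows))
        assert jk5 == pytest.approx(0.1)

    def test_editing_signature_empty(self):
        table, jk5 = editing_signature(_table([_rec(locus="IGL")]))
        assert table.empty and np.isnan(jk5)


class TestCdr3AndClonotypes:
    def test_charge_hand_counts(self):
        df = _table(
            [
                _rec(cdr3="CARDY", cell="c0"),   # R(+1), D(-1) -> 0
                _rec(cdr3="GGGGG", cell="c1"),   # 0
                _rec(cdr3="KRKE", cell="c2"),    # +3 -1 -> 2
            ]
        )
        props = cdr3_properties(df)
        assert list(props["charge"]) == [0, 0, 2]
        assert list(props["length"]) == [5, 5, 4]

    def test_histidine_flag(self):
        df = _table([_rec(cdr3="HHH", cell="c0")])
        assert cdr3_properties(df)["charge"].iloc[0] == 0
        assert cdr3_properties(df, include_histidine=True)["charge"].iloc[0] == 3

    def test_histogram_hand_tally(self):
        cdr3s = ["AAAA", "AAAA", "RRRR", "DDDD", "RKDE", "CCCC",
                 "WWWW", "YYYY", "KKKK", "EEEE"]
        df = _table([_rec(cdr3=c, cell=f"c{i}") for i, c in enumerate(cdr3s)])
        props = cdr3_properties(df)
        hist = props["charge"].value_counts().to_dict()
        assert hist == {0: 6, 4: 2, -4: 2}

    def test_all_distinct_clonotypes(self):
        df = _table([_rec(cdr3=f"AAA{c}", cell=f"c{i}") for i, c in enumerate("CDEF")])
        t = clonotype_table(df, "kappa_cdr3")
        assert len(t) == 4
        assert np.allclose(t["frequency"], 0.25)

    def test_injected_clone_mass(self, germline):
        """A 10% heavy clone tops the clonotype table at ~0.10 (n=5000)."""
        import bcrep
        import dataclasses

        preset = dataclasses.replace(
            bcrep.get_preset("ctrl"),
            unproductive_fraction={},
            clonal_expansion=bcrep.ClonalExpansion(1, 0.1, "Ighv10-1"),
        )
        cells = bcrep.simulate_cells(germline, preset, 5000, seed=22)
        rows = [
            _rec(
                locus="IGH",
                v=c.heavy.v_name,
                j=c.heavy.j_name,
                cdr3=c.heavy.junction_nt,  # truth key; uniqueness is what matters
                cell=c.cell_id,
            )
            for c in cells
        ]
        t = clonotype_table(_table(rows), "heavy_cdr3")
        top = t["frequency"].iloc[0]
        assert abs(top - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / 5000)

    def test_empty_clonotypes(self):
        t = clonotype_table(_table([]).reindex(columns=list(_rec().keys())), "heavy_cdr3")
        assert t.empty

    def test_paired_definition(self):
        rows = [
            _rec(locus="IGH", cdr3="HHHH", cell="c0"),
            _rec(locus="IGK", cdr3="KKKK", cell="c0"),
            _rec(locus="IGH", cdr3="HHHH", cell="c1"),
            _rec(locus="IGK", cdr3="KKKK", cell="c1"),
        ]
        t = clonotype_table(_table(rows), "paired_hl")
        assert len(t) == 1
        assert t["key"].iloc[0] == "HHHH|KKKK"
        assert t["count"].iloc[0] == 2


class TestIsotypeAndProductivity:
    def test_isotype_over_cells(self, germline):
        rows = [
            _rec(locus="IGK", cell="c0"),
            _rec(locus="IGL", v="Iglv1", j="Iglj1", cell="c1"),
            _rec(locus="IGL", v="Iglv1", j="Iglj3", cell="c2"),
            _rec(locus="IGK", productive=False, failure="stop_codon", cell="c3"),
        ]
        iso, fam = isotype_family_frequencies(_table(rows), germline)
        assert iso.total == 3  # c3 has no productive light chain
        assert iso["kappa"] == pytest.approx(1 / 3)
        assert fam["lambda1"] == pytest.approx(0.5)
        assert fam["lambda3"] == pytest.approx(0.5)

    def test_all_productive_fixture(self):
        df = _table([_rec(cell=f"c{i}") for i in range(5)])
        pf = productivity_fractions(df).set_index("locus")
        assert pf.loc["IGK", "unproductive"] == 0.0

    def test_decoys_only(self):
        df = _table([_rec(productive=False, failure="non_ig", cell=f"d{i}") for i in range(3)])
        pf = productivity_fractions(df).set_index("locus")
        assert pf.loc["non_ig", "unproductive"] == 1.0

    def test_shares_sum_to_one(self, ctrl_small):
        _, _, _, annotations = ctrl_small
        pf = productivity_fractions(annotations)
        total = pf["productive"] + pf["out_of_frame"] + pf["stop_codon"]
        ig = pf[pf["locus"] != "non_ig"]
        assert np.allclose(
            ig["productive"] + ig["out_of_frame"] + ig["stop_codon"], 1.0
        )

    def test_conservation_of_reads(self, ctrl_small):
        """Every raw read lands in exactly one productivity bucket."""
        _, reads, _, annotations = ctrl_small
        pf = productivity_fractions(annotations)
        assert pf["n_reads"].sum() == len(reads)
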