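"""Mutation curation, annotation flags, SASA, Fisher co-occurrence, expression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutassess import datasets
from mutassess import synthetic as syn
from mutassess.ensemble_io import AtomRecord, ConformationalEnsemble, ResidueID
from mutassess.genomics import (
    MutationMatrix,
    MutationParseError,
    MutationRecord,
    classify_expression,
    cooccurrence_fisher,
    filter_domain,
    parse_mutation_table,
    parse_protein_change,
    ptm_slim_annotate,
    revel_classify,
    shrake_rupley_sasa,
    unique_mutations,
)


class TestParsing:
    def test_protein_change_parsing(self):
        assert parse_protein_change("S184F") == ("S", 184, "F")
        assert parse_protein_change("p.S184F") == ("S", 184, "F")

    def test_malformed_change_raises_with_context(self, tmp_path):
        p = tmp_path / "muts.tsv"
        p.write_text("mutation\nS184\n")
        with pytest.raises(MutationParseError, match="row 2"):
            parse_mutation_table(p, "tsv")

    def test_maf_keeps_only_missense(self, tmp_path):
        p = tmp_path / "in.maf"
        rows = [
            ("ULK1", "S1", "Missense_Mutation", "p.S184F"),
            ("ULK1", "S2", "Silent", "p.S184S"),
            ("ULK1", "S3", "Nonsense_Mutation", "p.R137*"),
        ]
        p.write_text(
            "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tHGVSp_Short\n"
            + "\n".join("\t".join(r) for r in rows)
        )
        records = parse_mutation_table(p, "maf")
        assert [r.label for r in records] == ["S184F"]

    def test_maf_round_trip_from_generator(self, tmp_path):
        maf = tmp_path / "synthetic.maf"
        matrix = syn.make_mutation_data(
            60, ["G1", "G2"], {"G1": 0.3, "G2": 0.2}, seed=17, maf_path=maf
        )
        records = parse_mutation_table(maf, "maf")
        for g in ["G1", "G2"]:
            samples = {r.sample for r in records if r.gene == g}
            assert samples == set(matrix.data.index[matrix.data[g]])


class TestDomainFilter:
    def test_curated_table_yields_36_unique_domain_mutations(self):
        records = filter_domain(datasets.ulk1_mutations(), (8, 280))
        assert len(unique_mutations(records)) == 36

    def test_boundary_exclusion(self):
        inside = MutationRecord("G", "A", 280, "V")
        outside = MutationRecord("G", "A", 281, "V")
        kept = filter_domain([inside, outside], (8, 280))
        assert kept == [inside] and outside.in_domain is False

    def test_matches_interval_oracle_and_idempotent(self, rng):
        records = [
            MutationRecord("G", "A", int(p), "V") for p in rng.integers(1, 400, 80)
        ]
        kept = filter_domain(records, (8, 280))
        assert [r.position for r in kept] == [r.position for r in records if 8 <= r.position <= 280]
        assert filter_domain(kept, (8, 280)) == kept


class TestRevel:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.843, "damaging"), (0.04, "neutral"), (0.4, "damaging"), (None, "unscored")],
    )
    def test_cutoff_rules(self, score, expected):
        assert revel_classify(score, cutoff=0.4) == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_score(self, a, b):
        lo, hi = sorted((a, b))
        order = {"neutral": 0, "damaging": 1}
        assert order[revel_classify(lo)] <= order[revel_classify(hi)]


class TestAnnotationInterplay:
    def test_slim_range_start_position_covered(self):
        rec = MutationRecord("ULK1", "D", 279, "N")
        slim = pd.DataFrame({"name": ["IAP-binding motif"], "start": [279], "end": [283]})
        ptm_slim_annotate([rec], slim_table=slim)
        assert rec.slim_overlap == "IAP-binding motif"

    def test_phospho_gain_requires_exposure(self):
        rec_exposed = MutationRecord("ULK1", "P", 250, "S")
        rec_buried = MutationRecord("ULK1", "P", 250, "S")
        gain = pd.DataFrame({"position": [250], "residue": ["S"], "modification": ["phosphorylation by PKC"]})
        ptm_slim_annotate([rec_exposed], gain_table=gain, relative_sasa={250: 0.5})
        ptm_slim_annotate([rec_buried], gain_table=gain, relative_sasa={250: 0.05})
        assert rec_exposed.ptm_gained is True
        assert rec_buried.ptm_gained is False

    def test_ptm_abolition_flag(self):
        rec = MutationRecord("ULK1", "S", 195, "P")
        ptm = pd.DataFrame({"position": [195], "modification": ["phosphorylation"]})
        ptm_slim_annotate([rec], ptm_table=ptm)
        assert rec.ptm_abolished is True

    def test_no_table_hits_leaves_clean_flags(self):
        rec = MutationRecord("ULK1", "A", 28, "V")
        ptm_slim_annotate(
            [rec],
            ptm_table=pd.DataFrame({"position": [195], "modification": ["x"]}),
            slim_table=pd.DataFrame({"name": ["m"], "start": [279], "end": [283]}),
            gain_table=pd.DataFrame({"position": [1], "residue": ["S"], "modification": ["x"]}),
            relative_sasa={},
        )
        assert rec.ptm_abolished is False and rec.ptm_gained is False and rec.slim_overlap == ""

    def test_untouched_tables_stay_not_evaluated(self):
        rec = MutationRecord("ULK1", "A", 28, "V")
        ptm_slim_annotate([rec])
        assert rec.ptm_abolished is None and rec.ptm_gained is None and rec.slim_overlap is None


def _atom_ensemble(specs):
    """specs: list of (resname, atomname, element, xyz)."""
    atoms = []
    for i, (rn, an, el, xyz) in enumerate(specs):
        atoms.append(AtomRecord(ResidueID("A", i + 1, rn), an, el, np.asarray(xyz, float), 12.011))
    coords = np.stack([a.coordinates for a in atoms])[None]
    return ConformationalEnsemble(atoms, coords)


def quadrature_sasa_two_spheres(c1, r1, c2, r2, n=200_000, seed=0):
    """Independent dense Monte Carlo estimate of sphere-1 area outside sphere 2."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = np.asarray(c1) + r1 * v
    outside = np.linalg.norm(pts - np.asarray(c2), axis=1) >= r2
    return outside.mean() * 4 * math.pi * r1**2


class TestSASA:
    def test_isolated_atom_closed_form(self):
        ens = _atom_ensemble([("GLY", "CA", "C", (0, 0, 0))])
        out = shrake_rupley_sasa(ens)
        r = 1.87 + 1.4
        assert out.sasa_total.iloc[0] == pytest.approx(4 * math.pi * r**2, rel=1e-9)

    def test_buried_atom_near_zero(self):
        shell = []
        golden = (1 + 5**0.5) / 2
        for k in range(40):  # tight shell of carbons at 2.4 A
            z = 1 - 2 * (k + 0.5) / 40
            phi = 2 * math.pi * k / golden
            s = math.sqrt(1 - z * z)
            shell.append(("GLY", "CA", "C", (2.4 * s * math.cos(phi), 2.4 * s * math.sin(phi), 2.4 * z)))
        ens = _atom_ensemble([("GLY", "CA", "C", (0.0, 0.0, 0.0))] + shell)
        out = shrake_rupley_sasa(ens)
        assert out.sasa_total.iloc[0] == pytest.approx(0.0, abs=1.0)

    def test_two_overlapping_spheres_match_quadrature_oracle(self):
        c1, c2 = (0.0, 0.0, 0.0), (2.5, 0.0, 0.0)
        ens = _atom_ensemble([("GLY", "CA", "C", c1), ("GLY", "CA", "C", c2)])
        out = shrake_rupley_sasa(ens)
        r = 1.87 + 1.4
        expected = quadrature_sasa_two_spheres(c1, r, c2, r)
        assert out.sasa_total.iloc[0] == pytest.approx(expected, rel=0.02)

    def test_rotation_invariance(self):
        ens = syn.make_charged_pair_ensemble(100.0, 1)
        base = shrake_rupley_sasa(ens)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [30, 45, 60], degrees=True).as_matrix()
        rotated = ConformationalEnsemble(ens.atoms, ens.coords @ R.T)
        rot = shrake_rupley_sasa(rotated)
        assert np.allclose(rot.sasa_total, base.sasa_total, rtol=0.01)

    def test_unknown_element_raises(self):
        ens = _atom_ensemble([("GLY", "CA", "C", (0, 0, 0))])
        ens.atoms[0].element = "Xx"
        with pytest.raises(KeyError):
            shrake_rupley_sasa(ens)


def hypergeom_enumeration_p(table, alternative="greater"):
    """Exact Fisher p by full enumeration over admissible 2x2 tables."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = prob(a)
    if alternative == "greater":
        return sum(prob(x) for x in range(a, hi + 1))
    if alternative == "less":
        return sum(prob(x) for x in range(lo, a + 1))
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_perfect_overlap_exact_value(self):
        df = pd.DataFrame({"A": [True] * 4 + [False] * 6, "B": [True] * 4 + [False] * 6})
        _, p, table = cooccurrence_fisher(MutationMatrix(df), "A", "B")
        assert p == pytest.approx(1 / 210)
        assert table[0][0] == 4

    def test_degenerate_margin_p_is_one(self):
        df = pd.DataFrame({"A": [False] * 10, "B": [True] * 3 + [False] * 7})
        _, p, _ = cooccurrence_fisher(MutationMatrix(df), "A", "B")
        assert p == pytest.approx(1.0)

    def test_matches_full_enumeration_oracle(self, rng):
        for trial in range(20):
            df = pd.DataFrame(
                {
                    "A": rng.random(30) < 0.35,
                    "B": rng.random(30) < 0.25,
                }
            )
            for alt in ("greater", "less", "two-sided"):
                _, p, table = cooccurrence_fisher(MutationMatrix(df), "A", "B", alternative=alt)
                assert p == pytest.approx(hypergeom_enumeration_p(table, alt), rel=1e-9)

    def test_two_sided_label_symmetry(self, rng):
        df = pd.DataFrame({"A": rng.random(25) < 0.4, "B": rng.random(25) < 0.3})
        _, p_ab, _ = cooccurrence_fisher(MutationMatrix(df), "A", "B", "two-sided")
        _, p_ba, _ = cooccurrence_fisher(MutationMatrix(df), "B", "A", "two-sided")
        assert p_ab == pytest.approx(p_ba)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            cooccurrence_fisher(pd.DataFrame({"A": [], "B": []}), "A", "B")


class TestExpression:
    @pytest.mark.parametrize(
        "logfc,fdr,expected",
        [
            (0.8, 0.01, "up"),
            (-0.8, 0.01, "down"),
            (0.0, 0.001, "no_DE"),
            (0.8, 0.2, "no_DE"),
            (0.5, 0.05, "up"),  # inclusive boundaries
            (-0.5, 0.05, "down"),
        ],
    )
    def test_threshold_rules(self, logfc, fdr, expected):
        rows = pd.DataFrame({"gene": ["X"], "logFC": [logfc], "FDR": [fdr]})
        assert classify_expression(rows)[0].call == expected

    def test_missing_fdr_warns_no_de(self):
        rows = pd.DataFrame({"gene": ["X"], "logFC": [2.0], "FDR": [np.nan]})
        out = classify_expression(rows)
        assert out[0].call == "no_DE" and out[0].fdr is None

    def test_planted_calls_recovered(self, rng):
        truth = []
        rows = []
        for i in range(50):
            logfc = float(rng.normal(0, 1))
            fdr = float(rng.random() * 0.2)
            call = "up" if (logfc >= 0.5 and fdr <= 0.05) else "down" if (logfc <= -0.5 and fdr <= 0.05) else "no_DE"
            truth.append(call)
            rows.append({"gene": f"G{i}", "logFC": logfc, "FDR": fdr})
        out = classify_expression(pd.DataFrame(rows))
        assert [o.call for o in out] == truth
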