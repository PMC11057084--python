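"""Instrument selection, LD clumping, F statistics, and QC filters."""

import numpy as np
import pytest

from summr.errors import ValidationError
from summr.gwas_io import LDMatrix, pair_from_arrays
from summr.instruments import (
    SelectionParams,
    build_instrument_set,
    drop_outcome_associated,
    filter_weak,
    ld_clump,
    read_instrument_table,
    score_instruments,
    select_by_pvalue,
    variance_explained_and_f,
)

from conftest import make_table


class TestSelectByPvalue:
    def test_all_null_empty(self):
        tab = make_table(pval=(1.0, 1.0, 1.0))
        assert select_by_pvalue(tab) == []

    def test_boundary_strictly_excluded(self):
        tab = make_table(pval=(5e-6, 4.9e-6, 1e-3))
        assert select_by_pvalue(tab, 5e-6) == ["rs2"]

    def test_planted_hits_recovered(self):
        rng = np.random.default_rng(11)
        k, planted = 100, 7
        pvals = rng.uniform(1e-4, 1.0, k)
        hit_idx = rng.choice(k, planted, replace=False)
        pvals[hit_idx] = rng.uniform(1e-10, 4e-6, planted)
        tab = make_table(
            variant_id=[f"rs{i}" for i in range(k)],
            pos=list(range(1000, 1000 + k)),
            effect_allele=["A"] * k, other_allele=["G"] * k,
            eaf=[0.3] * k, beta=[0.1] * k, se=[0.02] * k, pval=list(pvals),
        )
        got = select_by_pvalue(tab)
        assert sorted(got) == sorted(f"rs{i}" for i in hit_idx)
        # ascending p-value order
        lookup = dict(zip(tab.data["variant_id"], tab.data["pval"]))
        assert [lookup[v] for v in got] == sorted(lookup[v] for v in got)


def _clump_table(pos, pvals, chrom="1"):
    k = len(pos)
    return make_table(
        variant_id=[f"rs{i}" for i in range(k)], pos=list(pos), chrom=chrom,
        effect_allele=["A"] * k, other_allele=["G"] * k, eaf=[0.3] * k,
        beta=[0.1] * k, se=[0.02] * k, pval=list(pvals),
    )


class TestLDClump:
    def test_linked_pair_keeps_smaller_p(self):
        tab = _clump_table([1000, 2000], [1e-8, 1e-6])
        r = np.sqrt(0.5)
        ld = LDMatrix(["rs0", "rs1"], np.array([[1, r], [r, 1]]))
        assert ld_clump(["rs0", "rs1"], tab, ld) == ["rs0"]

    def test_outside_window_both_kept(self):
        tab = _clump_table([1_000_000, 16_000_000], [1e-8, 1e-6])
        r = np.sqrt(0.9)
        ld = LDMatrix(["rs0", "rs1"], np.array([[1, r], [r, 1]]))
        assert set(ld_clump(["rs0", "rs1"], tab, ld)) == {"rs0", "rs1"}

    def test_different_chromosome_no_conflict(self):
        tab = make_table(
            variant_id=("rs0", "rs1"), pos=(1000, 2000), chrom=("1", "2"),
            effect_allele=("A", "A"), other_allele=("G", "G"), eaf=(0.3, 0.3),
            beta=(0.1, 0.1), se=(0.02, 0.02), pval=(1e-8, 1e-6),
        )
        r = 0.99
        ld = LDMatrix(["rs0", "rs1"], np.array([[1, r], [r, 1]]))
        assert set(ld_clump(["rs0", "rs1"], tab, ld)) == {"rs0", "rs1"}

    def test_missing_candidate_errors(self):
        tab = _clump_table([1000], [1e-8])
        with pytest.raises(ValidationError, match="rs9"):
            ld_clump(["rs9"], tab, None)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        tab = _clump_table(rng.integers(1, 5_000_000, 15), rng.uniform(1e-10, 1e-5, 15))
        ids = list(tab.data["variant_id"])
        A = rng.normal(size=(15, 15))
        corr = np.corrcoef(A @ A.T + 5 * np.eye(15))
        ld = LDMatrix(ids, corr)
        kept1 = ld_clump(ids, tab, ld, clump_r2=0.1)
        kept2 = ld_clump(ids[::-1], tab, ld, clump_r2=0.1)
        assert kept1 == kept2

    def test_identity_with_permissive_params(self):
        tab = _clump_table([1000, 1100, 1200], [1e-8, 1e-7, 1e-6])
        ids = list(tab.data["variant_id"])
        r = 0.9
        ld = LDMatrix(ids, np.full((3, 3), r) + (1 - r) * np.eye(3))
        kept = ld_clump(ids, tab, ld, clump_r2=1.0, window_bp=0)
        assert sorted(kept) == sorted(ids)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        """Greedy result satisfies the full pairwise constraint set, and every
        dropped candidate conflicts with a kept, smaller-p variant."""
        rng = np.random.default_rng(seed)
        k = 20
        tab = _clump_table(rng.integers(1, 30_000_000, k), rng.uniform(1e-12, 1e-5, k))
        ids = list(tab.data["variant_id"])
        A = rng.normal(size=(k, k + 5))
        corr = np.corrcoef(A)
        ld = LDMatrix(ids, corr)
        clump_r2, window = 0.2, 10_000_000
        kept = ld_clump(ids, tab, ld, clump_r2=clump_r2, window_bp=window)
        info = tab.data.set_index("variant_id")

        def conflict(a, b):
            if info.loc[a, "chrom"] != info.loc[b, "chrom"]:
                return False
            if abs(int(info.loc[a, "pos"]) - int(info.loc[b, "pos"])) > window:
                return False
            return ld.r2(a, b) >= clump_r2

        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert not conflict(a, b)
        for v in set(ids) - set(kept):
            assert any(
                conflict(v, w) and (info.loc[w, "pval"], w) < (info.loc[v, "pval"], v)
                for w in kept
            )


class TestVarianceExplainedAndF:
    def test_zero_beta(self):
        res = variance_explained_and_f(0.0, 0.02, 0.3, 1000)
        assert res.r2 == 0 and res.f == 0 and res.valid

    def test_hand_arithmetic(self):
        # eaf 0.5, z 0.2, n 1000, k 1: r2 = 0.02, f = 0.02*998/0.98
        res = variance_explained_and_f(0.2, 1.0, 0.5, 1000)
        assert res.r2 == pytest.approx(0.02)
        assert res.f == pytest.approx(0.02 * 998 / 0.98, rel=1e-12)
        assert res.f == pytest.approx(20.3673, abs=5e-5)

    def test_pathological_flagged_not_clamped(self):
        res = variance_explained_and_f(2.0, 1.0, 0.25, 1000)
        assert res.r2 == pytest.approx(1.5)
        assert not res.valid

    def test_normalized_formula_is_z_squared(self):
        res = variance_explained_and_f(5.0, 1.0, 0.3, 10_000, formula="normalized")
        assert res.f == pytest.approx(25.0, rel=1e-12)
        assert 0 < res.r2 < 1

    def test_monotone_in_z(self):
        fs = [
            variance_explained_and_f(z, 1.0, 0.3, 10_000, formula="normalized").f
            for z in (1.0, 2.0, 4.0, 6.0)
        ]
        assert fs == sorted(fs)

    def test_precondition_errors(self):
        with pytest.raises(ValidationError):
            variance_explained_and_f(0.1, 0.0, 0.3, 1000)
        with pytest.raises(ValidationError):
            variance_explained_and_f(0.1, 0.02, 0.3, 2)


class TestFilters:
    def test_filter_weak_boundary(self):
        tab = make_table(beta=(0.1, 0.1, 0.1))
        iset = score_instruments(tab, ["rs1", "rs2", "rs3"],
                                 SelectionParams(r2_formula="normalized"))
        iset.data["f_stat"] = [9.999, 10.0, 50.0]
        kept = filter_weak(iset, 10.0)
        assert list(kept.data["variant_id"]) == ["rs2", "rs3"]

    def test_drop_outcome_associated(self):
        pair = pair_from_arrays(
            [0.1, 0.1, 0.1], [0.02] * 3, [0.0, 0.16, 0.0], [0.02] * 3
        )
        out = drop_outcome_associated(pair)  # z = 8 -> p ~ 1.2e-15 < 5e-8
        assert out.n_snp == 2
        assert "dropped-outcome-associated" in out.log.values()

    def test_zero_threshold_removes_nothing(self):
        pair = pair_from_arrays([0.1] * 3, [0.02] * 3, [0.5] * 3, [0.02] * 3)
        assert drop_outcome_associated(pair, 0.0).n_snp == 3

    def test_null_outcome_nothing_removed(self):
        pair = pair_from_arrays([0.1] * 3, [0.02] * 3, [0.0] * 3, [0.02] * 3)
        assert drop_outcome_associated(pair).n_snp == 3


class TestBuildAndSerialize:
    def test_full_chain_and_tsv(self, tmp_path):
        from summr.synthetic_data import SimConfig, simulate_two_sample

        exp, _, _ = simulate_two_sample(SimConfig(seed=5, n_snp=40))
        iset = build_instrument_set(exp, None, SelectionParams(r2_formula="normalized"))
        assert (iset.data["f_stat"] >= 10).all()
        path = tmp_path / "inst.tsv"
        iset.to_tsv(path)
        back = read_instrument_table(path, "exposure")
        assert back.data["f_stat"].min() >= 10
        assert len(back) == len(iset)
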