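import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from plastevol import codonevol as ce, synthetic_data as sd
from plastevol.formats_io import ValidationError

STOPS = {"TAA", "TAG", "TGA"}  # table 11


def random_codon_pair_table(rng, n_codons, p_mut=0.12):
    """A random stop-free pair of coding sequences of n_codons codons."""
    while True:
        s1 = []
        for _ in range(n_codons):
            while True:
                c = "".join(rng.choice(list("ACGT"), 3))
                if c not in STOPS:
                    break
            s1.append(c)
        s1 = "".join(s1)
        s2 = list(s1)
        for i in range(len(s2)):
            if rng.random() < p_mut:
                s2[i] = str(rng.choice([b for b in "ACGT" if b != s2[i]]))
        s2 = "".join(s2)
        if all(s2[i : i + 3] not in STOPS for i in range(0, len(s2), 3)):
            return s1, s2


def brute_force_ng86(s1, s2):
    """Independent oracle: explicit enumeration of sites and of every
    ordering of single-base steps per codon, using Biopython translation."""
    from Bio.Seq import Seq

    def aa(codon):
        t = str(Seq(codon).translate(table=11))
        return None if t == "*" else t

    codons = [(s1[i : i + 3], s2[i : i + 3]) for i in range(0, len(s1), 3)]

    def syn_sites(c):
        s = 0.0
        for pos in range(3):
            for alt in "ACGT":
                if alt != c[pos]:
                    mut = c[:pos] + alt + c[pos + 1 :]
                    if aa(mut) is not None and aa(mut) == aa(c):
                        s += 1.0 / 3.0
        return s

    S = (sum(syn_sites(a) for a, _ in codons) + sum(syn_sites(b) for _, b in codons)) / 2
    N = 3 * len(codons) - S
    Sd = Nd = 0.0
    for a, b in codons:
        diffs = [i for i in range(3) if a[i] != b[i]]
        if not diffs:
            continue
        all_paths, valid = [], []
        for order in itertools.permutations(diffs):
            cur, syn, nonsyn, blocked = a, 0.0, 0.0, False
            for step, pos in enumerate(order):
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if step < len(order) - 1 and aa(nxt) is None:
                    blocked = True
                if aa(cur) is not None and aa(nxt) == aa(cur):
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            all_paths.append((syn, nonsyn))
            if not blocked:
                valid.append((syn, nonsyn))
        use = valid or all_paths
        Sd += sum(p[0] for p in use) / len(use)
        Nd += sum(p[1] for p in use) / len(use)
    return N, S, Nd, Sd


class TestNG86:
    def test_identical_sequences(self):
        r = ce.ng86_pair("ATGAAAGGG", "ATGAAAGGG")
        assert r.dn == 0.0 and r.ds == 0.0
        assert math.isnan(r.omega)

    def test_synonymous_third_position_change(self):
        # 10 codons, one synonymous change: ds > 0, dn = 0
        s1 = "ATGAAAGGGTTTCCCGATCATAGAGCTTGG"
        s2 = s1[:8] + "A" + s1[9:]  # GGG -> GGA (Gly, synonymous)
        r = ce.ng86_pair(s1, s2)
        assert r.dn == 0.0 and r.ds > 0.0
        N, S, Nd, Sd = brute_force_ng86(s1, s2)
        assert r.Sd == pytest.approx(Sd) and r.Nd == pytest.approx(Nd)
        assert r.S == pytest.approx(S) and r.N == pytest.approx(N)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_site_conservation_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        s1, s2 = random_codon_pair_table(rng, int(rng.integers(1, 15)))
        r = ce.ng86_pair(s1, s2)
        assert r.N + r.S == pytest.approx(3 * r.codons)
        back = ce.ng86_pair(s2, s1)
        assert back.Sd == pytest.approx(r.Sd)
        assert back.Nd == pytest.approx(r.Nd)
        assert back.S == pytest.approx(r.S)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError):
            ce.ng86_pair("ATGTAAGGG", "ATGAAAGGG")

    def test_terminal_stop_masked(self):
        r = ce.ng86_pair("ATGAAATAA", "ATGAAATGA")
        assert r.codons == 2

    def test_gap_codons_masked_pairwise(self):
        r = ce.ng86_pair("ATG---AAA", "ATGCCCAAA")
        assert r.codons == 2
        assert r.Nd == 0 and r.Sd == 0

    def test_saturated_proportion_reported_missing(self):
        # two codons, every third position changed synonymously -> pS >= 3/4
        r = ce.ng86_pair("GGTGGT", "GGCGGC")
        assert math.isnan(r.ds)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            ce.ng86_pair("ATGAAA", "ATG")


class TestFilterHighDs:
    @staticmethod
    def table(n_genes, rng):
        rows = []
        for g in range(n_genes):
            for t in range(3):
                rows.append(
                    {"gene": f"g{g:02d}", "taxon": f"t{t}", "ds": rng.random(), "dn": 0.0, "omega": 1.0}
                )
        return pd.DataFrame(rows)

    def test_removes_requested_count(self):
        table = self.table(68, np.random.default_rng(0))
        filtered = ce.filter_high_ds(table, n_remove=35)
        assert filtered["gene"].nunique() == 33

    def test_zero_removal_is_identity(self):
        table = self.table(10, np.random.default_rng(1))
        assert ce.filter_high_ds(table, n_remove=0).equals(table)

    def test_removal_set_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        table = self.table(20, rng)
        filtered = ce.filter_high_ds(table, n_remove=7)
        mean_ds = table.groupby("gene")["ds"].mean()
        expected_removed = set(mean_ds.sort_values(ascending=False).index[:7])
        assert set(table["gene"]) - set(filtered["gene"]) == expected_removed

    def test_removing_all_genes_rejected(self):
        table = self.table(5, np.random.default_rng(3))
        with pytest.raises(ValidationError):
            ce.filter_high_ds(table, n_remove=5)


class TestKruskalWallis:
    def test_worked_two_group_case(self):
        result = ce.kruskal_wallis([[1, 2], [3, 4]])
        assert result.H == pytest.approx(2.4)
        assert result.df == 1

    def test_identical_groups_give_h_zero_p_one(self):
        result = ce.kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert result.H == 0.0 and result.p_value == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [
                list(rng.choice(np.arange(10), size=rng.integers(2, 9)).astype(float))
                for _ in range(k)
            ]
            mine = ce.kruskal_wallis(groups)
            try:
                h_ref, p_ref = stats.kruskal(*groups)
            except ValueError:  # scipy refuses all-identical data
                continue
            assert mine.H == pytest.approx(h_ref, abs=1e-9)
            assert mine.p_value == pytest.approx(p_ref, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ce.kruskal_wallis([[1, 2]])
        with pytest.raises(ValidationError):
            ce.kruskal_wallis([[1], []])


class TestCategoryComparison:
    def test_single_category_refused(self):
        table = pd.DataFrame(
            {"gene": ["g"] * 2, "taxon": ["a", "b"], "dn": [0.1, 0.2],
             "ds": [0.1, 0.2], "omega": [1.0, 1.0]}
        )
        with pytest.raises(ValidationError):
            ce.category_rate_comparison(table, {"a": "C3", "b": "C3"})

    def test_unlabeled_taxon_rejected(self):
        table = pd.DataFrame(
            {"gene": ["g"], "taxon": ["a"], "dn": [0.1], "ds": [0.1], "omega": [1.0]}
        )
        with pytest.raises(ValidationError):
            ce.category_rate_comparison(table, {"b": "C3"})

    def test_cam_elevated_genes_recovered(self, toy_config, toy_bundle):
        rates = []
        for gene, pairs in toy_bundle.codon_alignments.items():
            ref = dict(pairs)[toy_config.reference_id]
            for taxon, seq in pairs:
                if taxon != toy_config.reference_id:
                    rates.append(ce.ng86_pair(ref, seq, gene=gene, taxon=taxon))
        table = ce.rates_to_frame(rates)
        filtered = ce.filter_high_ds(table, n_remove=toy_config.n_high_ds_genes)
        per_gene, _ = ce.category_rate_comparison(filtered, toy_config.categories)
        elevated = per_gene[per_gene["gene"].isin(sd.CAM_ELEVATED_GENES)]
        assert len(elevated) == len(sd.CAM_ELEVATED_GENES)
        assert (elevated["dn_mean_CAM"] > elevated["dn_mean_C3"]).all()
        assert (elevated["dn_mean_CAM"] > elevated["dn_mean_C3-CAM"]).all()
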