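"""Proteome filtering, id collapsing, five-group partition and concordance."""

import numpy as np
import pandas as pd
import pytest

from plateletome.proteome import (
    GROUP_LABELS,
    collapse_ids,
    concordance_spearman,
    filter_proteome,
    partition_groups,
    partition_percentages,
)


def proteome_df(rows):
    return pd.DataFrame(rows, columns=["protein_id", "abundance", "confidence"])


class TestFilterProteome:
    def test_low_confidence_removed_and_duplicates_collapsed(self):
        df = proteome_df(
            [("P1", 3.0, 99.0), ("P1", 7.5, 100.0), ("P2", 1.0, 95.0), ("P3", 2.0, 100.0)]
        )
        out = filter_proteome(df)
        assert out["protein_id"].tolist() == ["P1", "P3"]
        assert out.set_index("protein_id").loc["P1", "abundance"] == 7.5

    def test_empty_input(self):
        assert len(filter_proteome(proteome_df([]))) == 0

    def test_idempotent(self):
        df = proteome_df([("P1", 3.0, 99.0), ("P1", 7.5, 99.0), ("P2", 2.0, 100.0)])
        once = filter_proteome(df)
        twice = filter_proteome(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError, match="negative abundance"):
            filter_proteome(proteome_df([("P1", -1.0, 100.0)]))


class TestCollapseIds:
    def test_most_abundant_gene_wins(self):
        mapping = pd.DataFrame({"gene_id": ["gA", "gB"], "protein_id": ["P1", "P1"]})
        out = collapse_ids(mapping, pd.Series({"gA": 5.0, "gB": 8.0}))
        assert out.loc["P1", "gene_id"] == "gB"

    def test_one_to_one_passthrough(self):
        mapping = pd.DataFrame({"gene_id": ["gA", "gB"], "protein_id": ["P1", "P2"]})
        out = collapse_ids(mapping, pd.Series({"gA": 1.0, "gB": 2.0}))
        assert out["gene_id"].tolist() == ["gA", "gB"]

    def test_tie_breaks_to_lexicographically_smallest(self):
        mapping = pd.DataFrame({"gene_id": ["gB", "gA"], "protein_id": ["P1", "P1"]})
        out = collapse_ids(mapping, pd.Series({"gA": 5.0, "gB": 5.0}))
        assert out.loc["P1", "gene_id"] == "gA"


class TestPartition:
    def _toy(self):
        calls = pd.DataFrame(
            {
                "s1": [True, True, True, False, True],
                "s2": [True, True, False, False, True],
                "s3": [True, True, False, False, False],
            },
            index=["gAll", "gAllNoP", "gPart", "gOff", "gPartP"],
        )
        proteome = proteome_df([("P_all", 5.0, 100.0), ("P_only", 2.0, 100.0), ("P_part", 1.0, 99.0)])
        mapping = pd.DataFrame(
            {"gene_id": ["gAll", "gOff", "gPartP"], "protein_id": ["P_all", "P_ghost", "P_part"]}
        )
        return calls, proteome, mapping

    def test_five_groups_at_n_equals_3(self):
        calls, proteome, mapping = self._toy()
        groups = partition_groups(calls, proteome, mapping)
        assert groups["both_all10"] == {"P_all"}
        assert groups["mrna_all10_no_protein"] == {"gAllNoP"}
        assert groups["protein_no_mrna"] == {"P_only"}
        assert groups["mrna_1to9_no_protein"] == {"gPart"}
        assert groups["protein_and_mrna_1to9"] == {"P_part"}

    def test_groups_disjoint_and_protein_side_partitions_proteome(self):
        calls, proteome, mapping = self._toy()
        groups = partition_groups(calls, proteome, mapping)
        all_ids = [i for g in GROUP_LABELS for i in groups[g]]
        assert len(all_ids) == len(set(all_ids))
        protein_side = groups["both_all10"] | groups["protein_no_mrna"] | groups["protein_and_mrna_1to9"]
        assert protein_side == set(proteome["protein_id"])
        # transcript-side union covers every gene expressed somewhere and not represented by a protein
        expressed = set(calls.index[calls.any(axis=1)])
        transcript_side = groups["mrna_all10_no_protein"] | groups["mrna_1to9_no_protein"]
        assert transcript_side == expressed - {"gAll", "gPartP"}

    def test_unknown_mapping_ids_warn_and_skip(self):
        calls, proteome, mapping = self._toy()
        mapping = pd.concat(
            [mapping, pd.DataFrame({"gene_id": ["gNope"], "protein_id": ["P_all"]})], ignore_index=True
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            groups = partition_groups(calls, proteome, mapping)
        assert groups["both_all10"] == {"P_all"}


class TestConcordance:
    def test_monotone_pairs(self):
        pairs = pd.DataFrame({"transcript_abundance": [1.0, 2.0, 3.0], "protein_abundance": [10.0, 20.0, 30.0]})
        rho, _ = concordance_spearman(pairs)
        assert rho == pytest.approx(1.0)

    def test_hand_computed_rank_example(self):
        # ranks x=(1,2,3), y=(3,1,2) -> rho = -0.5
        pairs = pd.DataFrame({"transcript_abundance": [1.0, 2.0, 3.0], "protein_abundance": [3.0, 1.0, 2.0]})
        rho, _ = concordance_spearman(pairs)
        assert rho == pytest.approx(-0.5)

    def test_too_few_or_constant_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            concordance_spearman(pd.DataFrame({"transcript_abundance": [1.0], "protein_abundance": [1.0]}))
        with pytest.raises(ValueError, match="constant"):
            concordance_spearman(
                pd.DataFrame({"transcript_abundance": [1.0, 1.0, 1.0], "protein_abundance": [1.0, 2.0, 3.0]})
            )

    @pytest.mark.parametrize("rho_g", [0.0, 0.3, 0.8])
    def test_copula_parameter_recovery(self, rho_g):
        """Planted Gaussian-copula correlations are recovered within 3 SE at n=2,000."""
        from plateletome.simulate import _copula_abundances

        target = 6 / np.pi * np.arcsin(rho_g / 2)
        n = 2000
        # Fieller SE for Spearman's Fisher z
        se = np.sqrt((1 + target**2 / 2) / (n - 3))
        hits = 0
        for ss in np.random.SeedSequence(77).spawn(10):
            rng = np.random.default_rng(ss)
            x = np.exp(2 * rng.standard_normal(n))
            y = _copula_abundances(x, rho_g, rng)
            rho, _ = concordance_spearman(
                pd.DataFrame({"transcript_abundance": x, "protein_abundance": y})
            )
            z_err = abs(np.arctanh(rho) - np.arctanh(target)) / se
            hits += z_err <= 3
        assert hits == 10


def test_partition_percentages_from_headline_counts():
    sizes = {
        "both_all10": 2338,
        "mrna_all10_no_protein": 3226,
        "protein_no_mrna": 432,
        "mrna_1to9_no_protein": 3634,
        "protein_and_mrna_1to9": 774,
    }
    pct = partition_percentages(sizes)
    assert pct["n_proteome"] == 2338 + 432 + 774 == 3544
    assert pct["n_mrna_all_samples"] == 2338 + 3226 == 5564
    assert pct["pct_proteins_with_mrna_any"] == pytest.approx(100 * 3112 / 3544)
    assert pct["pct_proteins_with_mrna_all_samples"] == pytest.approx(100 * 2338 / 3544)
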