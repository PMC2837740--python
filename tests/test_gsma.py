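"""PAGE statistic, enrichment matrices, set ordering, and GMT I/O."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anro.gsma import (
    GeneSet,
    GeneSetCollection,
    enrichment_significance,
    gsma_matrix,
    page_z,
    read_gmt,
    sort_by_first_appearance,
    write_gmt,
)


def brute_force_page(set_genes, logratios):
    """Straight-line recomputation with the stdlib, independent of the pipeline."""
    universe = {g: v for g, v in logratios.items() if v == v}
    vals = list(universe.values())
    members = sorted({g.strip().upper() for g in set_genes} & set(universe))
    in_set = [universe[g] for g in members]
    m = len(in_set)
    mean = sum(vals) / len(vals)
    sigma = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
    z = (statistics.median(in_set) - statistics.median(vals)) * m**0.5 / sigma
    return z


@pytest.fixture()
def five_gene_contrast():
    return pd.Series([-2.0, -1.0, 0.0, 1.0, 2.0], index=list("ABCDE"))


class TestPageZ:
    def test_hand_example(self, five_gene_contrast):
        comp = page_z(["D", "E"], five_gene_contrast)
        assert comp.sm == 1.5
        assert comp.mu == 0.0
        assert comp.sigma == pytest.approx(np.sqrt(2.5))
        assert comp.m == 2
        assert comp.z == pytest.approx(1.342, abs=1e-3)

    def test_set_at_universe_median_scores_zero(self, five_gene_contrast):
        assert page_z(["B", "D"], five_gene_contrast).z == pytest.approx(0.0)

    def test_shift_invariance(self, five_gene_contrast):
        z0 = page_z(["D", "E"], five_gene_contrast).z
        z1 = page_z(["D", "E"], five_gene_contrast + 17.3).z
        assert z1 == pytest.approx(z0, abs=1e-12)

    def test_absent_members_dropped(self, five_gene_contrast):
        comp = page_z(["D", "E", "NOT_MEASURED"], five_gene_contrast)
        assert comp.m == 2

    def test_empty_intersection_raises(self, five_gene_contrast):
        with pytest.raises(ValueError):
            page_z(["X", "Y"], five_gene_contrast)

    def test_degenerate_contrast_raises(self):
        flat = pd.Series([1.0, 1.0, 1.0], index=list("ABC"))
        with pytest.raises(ValueError, match="zero SD"):
            page_z(["A"], flat)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(5, 60))
            genes = [f"G{i}" for i in range(n)]
            lr = pd.Series(rng.normal(size=n), index=genes)
            m = int(rng.integers(1, n))
            members = list(rng.choice(genes, size=m, replace=False))
            assert page_z(members, lr).z == pytest.approx(
                brute_force_page(members, lr), abs=1e-12
            )

    @settings(deadline=None, max_examples=40)
    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_positive_affine_invariance(self, a, b):
        lr = pd.Series([-2.0, -1.0, 0.0, 1.0, 2.0, 3.5], index=list("ABCDEF"))
        z0 = page_z(["E", "F"], lr).z
        z1 = page_z(["E", "F"], a * lr + b).z
        assert z1 == pytest.approx(z0, rel=1e-9, abs=1e-9)


class TestGsmaMatrix:
    def test_single_cell_reduces_to_page_z(self, five_gene_contrast):
        coll = GeneSetCollection([GeneSet("S", "d", ["D", "E"])])
        table = five_gene_contrast.to_frame("C1")
        result = gsma_matrix(coll, table)
        assert result.z.loc["S", "C1"] == pytest.approx(1.342, abs=1e-3)
        assert not result.missing.loc["S", "C1"]

    def test_unmeasured_set_flagged_missing(self, five_gene_contrast):
        coll = GeneSetCollection(
            [GeneSet("S", "d", ["D"]), GeneSet("GHOST", "d", ["X", "Y"])]
        )
        result = gsma_matrix(coll, five_gene_contrast.to_frame("C1"))
        assert result.missing.loc["GHOST", "C1"]
        assert np.isnan(result.z.loc["GHOST", "C1"])

    def test_empty_collection_raises(self, five_gene_contrast):
        with pytest.raises(ValueError):
            gsma_matrix(GeneSetCollection([]), five_gene_contrast.to_frame("C1"))

    def test_planted_sets_outrank_null(self, experiment, processed):
        from anro.simulate import generate_genesets

        _, _, _, annot, truth = experiment
        coll = generate_genesets(truth, n_planted=4, n_null=10, set_size=15, seed=30)
        from anro.preprocess import log_ratio

        lr = log_ratio(processed["nro"]["matrix"], annot, 0.0)
        lr48 = lr[[48.0]].rename(columns={48.0: "NRO_48h"})
        result = gsma_matrix(coll, lr48)
        z = result.z["NRO_48h"]
        persisting = [n for n in coll.names if n.startswith("PLANTED_") and "TRANSIENT" not in n]
        nulls = [n for n in coll.names if n.startswith("NULL_")]
        assert z.loc[persisting].abs().min() > z.loc[nulls].abs().max()

    def test_null_sets_centered(self, experiment, processed):
        from anro.preprocess import log_ratio
        from anro.simulate import generate_genesets

        _, _, _, annot, truth = experiment
        coll = generate_genesets(truth, n_planted=0, n_null=40, set_size=20, seed=31)
        lr = log_ratio(processed["nro"]["matrix"], annot, 0.0)
        result = gsma_matrix(coll, lr[[48.0]])
        z = result.z.iloc[:, 0]
        se = z.std(ddof=1) / np.sqrt(len(z))
        assert abs(z.mean()) < 3 * se + 1e-9


class TestEnrichmentSignificance:
    def test_reference_p_values(self):
        coll = GeneSetCollection([GeneSet("S", "d", ["C"])])
        lr = pd.Series([-1.0, 0.0, 1.0, 2.0, -2.0], index=list("ABCDE"))
        result = gsma_matrix(coll, lr.to_frame("C1"))
        result.z.loc["S", "C1"] = 0.0
        out = enrichment_significance(result)
        assert out.p.loc["S", "C1"] == pytest.approx(1.0)
        result.z.loc["S", "C1"] = 1.959964
        out = enrichment_significance(result)
        assert out.p.loc["S", "C1"] == pytest.approx(0.05, abs=1e-6)


class TestSortByFirstAppearance:
    def _result(self, zrows):
        cols = ["NRO_1h", "NRO_3h", "NRO_48h"]
        z = pd.DataFrame(zrows, columns=cols)
        shape = z.shape
        from anro.gsma import EnrichmentResult

        return EnrichmentResult(
            z=z,
            sm=z * np.nan,
            m=z.notna().astype(int),
            mu=pd.Series(0.0, index=cols),
            sigma=pd.Series(1.0, index=cols),
            missing=z.isna(),
        )

    def _meta(self):
        return pd.DataFrame(
            {
                "contrast": ["NRO_1h", "NRO_3h", "NRO_48h"],
                "rna_source": ["NRO"] * 3,
                "timepoint_hr": [1.0, 3.0, 48.0],
            }
        )

    def test_earlier_first_appearance_sorts_first(self):
        result = self._result(
            pd.DataFrame(
                {"NRO_1h": [0.0, 3.0], "NRO_3h": [3.0, 3.0], "NRO_48h": [0.0, 0.0]},
                index=["LATER", "SOONER"],
            )
        )
        order = sort_by_first_appearance(result, self._meta(), z_threshold=2.0)
        assert order == ["SOONER", "LATER"]

    def test_never_significant_fall_back_to_final_z(self):
        result = self._result(
            pd.DataFrame(
                {"NRO_1h": [0.0, 0.0], "NRO_3h": [0.0, 0.0], "NRO_48h": [0.5, 1.5]},
                index=["WEAK", "STRONG"],
            )
        )
        order = sort_by_first_appearance(result, self._meta(), z_threshold=2.0)
        assert order == ["STRONG", "WEAK"]

    def test_requires_nro_columns(self):
        result = self._result(
            pd.DataFrame({"NRO_1h": [1.0], "NRO_3h": [1.0], "NRO_48h": [1.0]})
        )
        meta = self._meta()
        meta["rna_source"] = "TOTAL"
        with pytest.raises(ValueError):
            sort_by_first_appearance(result, meta)


class TestGmtIO:
    def test_parse_line(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SETA\tdesc\tTP53\tMYC\n")
        coll = read_gmt(p)
        assert coll["SETA"].genes == ["TP53", "MYC"]

    def test_lowercase_members_uppercased(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SETA\tdesc\ttp53\tMyc\n")
        assert read_gmt(p)["SETA"].genes == ["TP53", "MYC"]

    def test_round_trip_identity(self, tmp_path):
        coll = GeneSetCollection(
            [
                GeneSet("ALPHA", "first", ["TP53", "MYC", "EGFR"]),
                GeneSet("BETA", "second", ["GAPDH"]),
            ]
        )
        write_gmt(coll, tmp_path / "x.gmt")
        assert read_gmt(tmp_path / "x.gmt") == coll

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("NAME_ONLY\tdesc\n")
        with pytest.raises(ValueError, match=">= 3"):
            read_gmt(p)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S\td\tA\nS\td\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)
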