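"""Tryptic digestion, molecular weight, and response-factor quantification."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomconcord.proteins import (
    PEPTIDE_COLUMNS,
    aggregate_replicates,
    allpeptide_quantify,
    apply_class_exclusions,
    detected_set,
    molecular_weight,
    top3_quantify,
    tryptic_digest,
)
from venomconcord.types import ProteinQuantResult, StandardSpec


def oracle_digest(seq: str, missed: int) -> list[str]:
    """Independent rule enumerator: explicit scan + adjacent concatenation."""
    frags, cur = [], ""
    for i, ch in enumerate(seq):
        cur += ch
        if ch in "KR" and not (i + 1 < len(seq) and seq[i + 1] == "P"):
            frags.append(cur)
            cur = ""
    if cur:
        frags.append(cur)
    out = []
    for k in range(1, missed + 2):
        for i in range(len(frags) - k + 1):
            out.append("".join(frags[i : i + k]))
    return out


class TestTrypticDigest:
    @pytest.mark.parametrize(
        "seq, missed, expected",
        [
            ("MKTAYRGG", 0, ["MK", "TAYR", "GG"]),
            ("AKPR", 0, ["AKPR"]),  # KP blocks cleavage; terminal R ends the chain
            ("MKTAYRGG", 1, ["MK", "TAYR", "GG", "MKTAYR", "TAYRGG"]),
            ("GGG", 0, ["GGG"]),
            ("KKK", 0, ["K", "K", "K"]),
        ],
    )
    def test_rule_examples(self, seq, missed, expected):
        assert tryptic_digest(seq, missed) == expected

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            tryptic_digest("", 0)
        with pytest.raises(ValueError):
            tryptic_digest("MKR", -1)

    @given(
        seq=st.text(alphabet="ACKRPGW", min_size=1, max_size=40),
        missed=st.integers(min_value=0, max_value=2),
    )
    @settings(max_examples=500, derandomize=True)
    def test_matches_bruteforce_enumerator(self, seq, missed):
        assert tryptic_digest(seq, missed) == oracle_digest(seq, missed)


class TestMolecularWeight:
    def test_reference_values(self):
        # average residue masses + one water
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.02)
        assert molecular_weight("GG") == pytest.approx(132.12, abs=0.02)

    def test_rejects_empty_and_unknown(self):
        with pytest.raises(ValueError):
            molecular_weight("")
        with pytest.raises(ValueError):
            molecular_weight("GZX")


def make_table(rows):
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


STD = StandardSpec(protein_id="STD", sequence="MSTELAVNKGFDQWIHRAVLYPESGK", load_fmol=50.0)


def std_rows(rep, intensities=(500_000.0, 300_000.0, 200_000.0)):
    return [
        (rep, "STD", f"PEP{i}K", 10.0 - i, inten, 0.0)
        for i, inten in enumerate(intensities)
    ]


class TestTop3:
    def test_response_factor_arithmetic(self):
        # standard top-3 sums to 1e6 -> RF = 5e-5 fmol/unit; protein top-3
        # sums to 4e5 -> 20 fmol
        rows = std_rows(1) + [
            (1, "P1", "AAAK", 3.0, 250_000.0, 0.0),
            (1, "P1", "CCCK", 2.0, 100_000.0, 0.0),
            (1, "P1", "DDDK", 1.0, 50_000.0, 0.0),
            (1, "P1", "EEEK", 0.5, 25_000.0, 0.0),  # 4th-ranked, ignored
        ]
        out = top3_quantify(make_table(rows), STD)
        assert out[1]["P1"] == pytest.approx(20.0, rel=1e-12)

    def test_fewer_than_three_peptides_excluded(self):
        rows = std_rows(1) + [
            (1, "P1", "AAAK", 3.0, 250_000.0, 0.0),
            (1, "P1", "CCCK", 2.0, 100_000.0, 0.0),
        ]
        assert "P1" not in top3_quantify(make_table(rows), STD)[1]

    def test_protein_matching_standard_intensities_gives_load(self):
        rows = std_rows(1) + [
            (1, "P1", pep, sc, inten, 0.0)
            for (_, _, pep, sc, inten, _) in std_rows(1)
        ]
        assert top3_quantify(make_table(rows), STD)[1]["P1"] == pytest.approx(50.0)

    def test_standard_with_too_few_peptides_errors(self):
        rows = std_rows(1, intensities=(1e6, 2e5)) + [
            (1, "P1", "AAAK", 3.0, 1e5, 0.0)
        ]
        with pytest.raises(ValueError, match="top-3"):
            top3_quantify(make_table(rows), STD)

    def test_top3_selected_by_score_not_intensity(self):
        rows = std_rows(1) + [
            (1, "P1", "AAAK", 5.0, 10_000.0, 0.0),
            (1, "P1", "CCCK", 4.0, 10_000.0, 0.0),
            (1, "P1", "DDDK", 3.0, 10_000.0, 0.0),
            (1, "P1", "EEEK", 1.0, 900_000.0, 0.0),  # huge but low score
        ]
        out = top3_quantify(make_table(rows), STD)
        assert out[1]["P1"] == pytest.approx(50.0 / 1e6 * 30_000.0)


class TestAllPeptide:
    def test_response_factor_arithmetic(self):
        # MW_std=36000, load=50 -> 1.8e6 fg; std total 2e6 -> RF 0.9 fg/unit;
        # protein total 1e6, MW 30000 -> 9e5 fg -> 30 fmol
        rows = std_rows(1, intensities=(1_000_000.0, 600_000.0, 400_000.0)) + [
            (1, "P1", "AAAK", 3.0, 700_000.0, 0.0),
            (1, "P1", "CCCK", 2.0, 300_000.0, 0.0),
        ]
        mw = {"STD": 36_000.0, "P1": 30_000.0}
        out = allpeptide_quantify(make_table(rows), STD, mw)
        assert out[1]["P1"] == pytest.approx(30.0, rel=1e-12)

    def test_same_intensity_and_mw_as_standard_gives_load(self):
        rows = std_rows(1) + [
            (1, "P1", "AAAK", 3.0, 1_000_000.0, 0.0),
        ]
        mw = {"STD": 36_000.0, "P1": 36_000.0}
        assert allpeptide_quantify(make_table(rows), STD, mw)[1]["P1"] == pytest.approx(50.0)

    def test_replicate_scale_invariance(self):
        rows = std_rows(1) + [(1, "P1", "AAAK", 3.0, 123_456.0, 0.0)]
        mw = {"STD": 36_000.0, "P1": 20_000.0}
        base = allpeptide_quantify(make_table(rows), STD, mw)[1]["P1"]
        scaled_rows = [
            (rep, pid, pep, sc, inten * 2.0, fpr)
            for rep, pid, pep, sc, inten, fpr in rows
        ]
        doubled = allpeptide_quantify(make_table(scaled_rows), STD, mw)[1]["P1"]
        assert doubled == pytest.approx(base, rel=1e-14)

    def test_missing_mw_errors(self):
        rows = std_rows(1) + [(1, "P1", "AAAK", 3.0, 1e5, 0.0)]
        with pytest.raises(ValueError, match="molecular weight"):
            allpeptide_quantify(make_table(rows), STD, {"STD": 36_000.0})


class TestAggregate:
    def test_mean_and_cv(self):
        per_rep = {1: {"P": 10.0}, 2: {"P": 10.0}, 3: {"P": 10.0}}
        (res,) = aggregate_replicates(per_rep, 3)
        assert res.mean_fmol == 10.0 and res.cv == 0.0 and res.detected_all_replicates

        per_rep = {1: {"P": 8.0}, 2: {"P": 10.0}, 3: {"P": 12.0}}
        (res,) = aggregate_replicates(per_rep, 3)
        assert res.mean_fmol == pytest.approx(10.0)
        assert res.cv == pytest.approx(0.2)  # sample sd = 2

    def test_partial_detection_flagged(self):
        per_rep = {1: {"P": 8.0}, 2: {"P": 10.0}, 3: {}}
        (res,) = aggregate_replicates(per_rep, 3)
        assert not res.detected_all_replicates

    def test_matches_bruteforce_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            vals = rng.lognormal(0, 1, 3)
            per_rep = {r + 1: {"P": float(v)} for r, v in enumerate(vals)}
            (res,) = aggregate_replicates(per_rep, 3)
            assert res.mean_fmol == pytest.approx(sum(vals) / 3)
            mean = sum(vals) / 3
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 2)
            assert res.cv == pytest.approx(sd / mean)


class TestExclusionsAndDetection:
    def _results(self, ids):
        return [
            ProteinQuantResult(i, [1.0], 1.0, 0.0, [1], True) for i in ids
        ]

    def test_bpp_removed_unknown_retained(self):
        fams = {"a": "BPP", "b": "SVMP", "c": "weirdo", "d": ""}
        kept = apply_class_exclusions(self._results("abcd"), fams)
        assert [r.protein_id for r in kept] == ["b", "c", "d"]

    def test_empty_exclusion_set_is_identity(self):
        fams = {"a": "BPP", "b": "CNP"}
        kept = apply_class_exclusions(self._results("ab"), fams, classes=set())
        assert [r.protein_id for r in kept] == ["a", "b"]

    def test_detected_requires_zero_fpr(self):
        table = make_table(
            [
                (2, "P1", "AAAK", 1.0, 1e5, 0.0),  # only in replicate 2
                (1, "P2", "CCCK", 1.0, 1e5, 0.02),
                (2, "P2", "CCCK", 1.0, 1e5, 0.01),
            ]
        )
        assert detected_set(table) == {"P1"}
        assert detected_set(make_table([])) == set()
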