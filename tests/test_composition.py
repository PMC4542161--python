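"""Within-class percentages, %change, the >1-point filter, side-chain fractions."""

import numpy as np
import pandas as pd
import pytest

import nashlipidomics as nl
from nashlipidomics.catalogue import LipidCatalogue, parse_chain_assignment, parse_species_name
from nashlipidomics.composition import acyl_multiplicity


def _mini_cat(*specs: tuple[str, str]) -> LipidCatalogue:
    return LipidCatalogue([
        parse_species_name(name).with_chains(parse_chain_assignment(chains))
        for name, chains in specs])


def _uniform_table(values: dict[str, float], samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame({s: list(values.values()) for s in samples},
                        index=list(values)).rename_axis("name")


@pytest.fixture()
def pc_cat():
    return _mini_cat(("32:0PC", "16:0/16:0"), ("36:2PC", "18:0/18:2"),
                     ("34:1PC", "16:0/18:1"), ("38:3PC-b", "n.d."))


# ---------------------------------------------------------------------------
# percentages

def test_single_species_class_is_100_percent(sheet_8w):
    cat = _mini_cat(("34:1PC", "16:0/18:1"))
    norm = _uniform_table({"34:1PC": 3.0}, list(sheet_8w.index))
    pct = nl.species_percent_within_class(norm, cat, sheet_8w, "PC", ("HFD", 8))
    assert pct.loc["34:1PC"] == pytest.approx(100.0)


def test_equal_species_split_fifty_fifty(sheet_8w):
    cat = _mini_cat(("32:0PC", "16:0/16:0"), ("34:1PC", "16:0/18:1"))
    norm = _uniform_table({"32:0PC": 2.0, "34:1PC": 2.0}, list(sheet_8w.index))
    pct = nl.species_percent_within_class(norm, cat, sheet_8w, "PC", ("STAM", 8))
    assert np.allclose(pct, [50.0, 50.0])


def test_three_species_hand_worked_ratios(sheet_8w, pc_cat):
    norm = _uniform_table({"32:0PC": 1.0, "36:2PC": 2.0, "34:1PC": 5.0,
                           "38:3PC-b": 0.0}, list(sheet_8w.index))
    pct = nl.species_percent_within_class(norm, pc_cat, sheet_8w, "PC", ("HFD", 8))
    assert pct.loc["32:0PC"] == pytest.approx(100 / 8)
    assert pct.loc["36:2PC"] == pytest.approx(200 / 8)
    assert pct.loc["34:1PC"] == pytest.approx(500 / 8)
    assert pct.sum() == pytest.approx(100.0)


def test_percent_invariant_to_per_sample_rescaling(sheet_8w, pc_cat, rng):
    samples = list(sheet_8w.index)
    norm = pd.DataFrame(rng.uniform(0.5, 4.0, size=(4, len(samples))),
                        index=["32:0PC", "36:2PC", "34:1PC", "38:3PC-b"],
                        columns=samples)
    scaled = norm * rng.uniform(0.1, 10.0, size=len(samples))
    a = nl.species_percent_within_class(norm, pc_cat, sheet_8w, "PC", ("HFD", 8))
    b = nl.species_percent_within_class(scaled, pc_cat, sheet_8w, "PC", ("HFD", 8))
    assert np.allclose(a, b)


def test_zero_class_total_rejected(sheet_8w, pc_cat):
    norm = _uniform_table({"32:0PC": 0.0, "36:2PC": 0.0, "34:1PC": 0.0,
                           "38:3PC-b": 0.0}, list(sheet_8w.index))
    with pytest.raises(ZeroDivisionError):
        nl.species_percent_within_class(norm, pc_cat, sheet_8w, "PC", ("HFD", 8))


# ---------------------------------------------------------------------------
# %change and the large-change filter

@pytest.mark.parametrize("ref, test, expected", [
    (0.74, 0.34, -0.40),   # published 34:1PE row
    (1.06, 1.09, +0.03),   # published 32:0PC row
    (5.0, 5.0, 0.0),
])
def test_percent_change_examples(ref, test, expected):
    assert nl.percent_change(ref, test) == pytest.approx(expected)


def test_percent_change_antisymmetry(rng):
    for _ in range(50):
        x, y = rng.uniform(0, 40, size=2)
        assert nl.percent_change(x, y) == pytest.approx(-nl.percent_change(y, x))


def test_flag_large_changes_sorted_descending():
    changes = pd.Series({"a": -7.9, "b": 0.5, "c": 3.5, "d": -1.01, "e": 1.0})
    assert nl.flag_large_changes(changes, 1.0) == ["a", "c", "d"]
    assert nl.flag_large_changes(changes, 100.0) == []
    with pytest.raises(ValueError):
        nl.flag_large_changes(changes, -1.0)


def test_published_panels_have_seven_large_movers_each(panel):
    for cls in ("PC", "PE"):
        sub = panel[panel["class"] == cls]
        change = sub["pct_stam"] - sub["pct_hfd"]
        flagged = nl.flag_large_changes(change, threshold=1.0)
        assert len(flagged) == 7, (cls, flagged)


def test_published_large_movers_all_carry_palmitate_or_stearate(panel, cat):
    """Every >1-point mover has a 16:0 or 18:0 side chain."""
    for cls in ("PC", "PE"):
        sub = panel[panel["class"] == cls]
        change = sub["pct_stam"] - sub["pct_hfd"]
        for name in nl.flag_large_changes(change, threshold=1.0):
            sp = cat.get(name)
            keys = {a.key for chains in sp.chain_assignments for a in chains}
            assert keys & {"16:0", "18:0"}, name


def test_composition_profile_round_trip(sheet_8w, pc_cat, rng):
    samples = list(sheet_8w.index)
    norm = pd.DataFrame(rng.uniform(0.5, 4.0, size=(4, len(samples))),
                        index=["32:0PC", "36:2PC", "34:1PC", "38:3PC-b"],
                        columns=samples)
    prof = nl.composition_profile(norm, pc_cat, sheet_8w, "PC",
                                  ("HFD", 8), ("STAM", 8))
    assert prof["pct_ref"].sum() == pytest.approx(100.0)
    assert prof["pct_test"].sum() == pytest.approx(100.0)
    assert np.allclose(prof["pct_change"], prof["pct_test"] - prof["pct_ref"])


# ---------------------------------------------------------------------------
# side-chain fractions

def test_single_species_fraction_is_half(sheet_8w):
    cat = _mini_cat(("34:1PC", "16:0/18:1"))
    norm = _uniform_table({"34:1PC": 3.0}, list(sheet_8w.index))
    assert nl.sidechain_fraction(norm, cat, sheet_8w, "PC", "16:0",
                                 ("HFD", 8)) == pytest.approx(0.5)


def test_homo_diacyl_counts_twice(sheet_8w):
    cat = _mini_cat(("32:0PC", "16:0/16:0"), ("36:2PC", "18:0/18:2"))
    norm = _uniform_table({"32:0PC": 1.0, "36:2PC": 1.0}, list(sheet_8w.index))
    # 16:0 appears twice in one of two equal species: 2 / (2 x 2)
    assert nl.sidechain_fraction(norm, cat, sheet_8w, "PC", "16:0",
                                 ("HFD", 8)) == pytest.approx(0.5)
    # presence weighting counts the species once
    assert nl.sidechain_fraction(norm, cat, sheet_8w, "PC", "16:0", ("HFD", 8),
                                 weighting="presence") == pytest.approx(0.25)


def test_acyl_multiplicity_rules():
    sp = parse_species_name("32:2PC").with_chains(
        parse_chain_assignment("14:0/18:2 16:1/16:1"))
    # equal split over alternatives: (0 + 2) / 2 matches of 16:1
    assert acyl_multiplicity(sp, "16:1") == pytest.approx(1.0)
    assert acyl_multiplicity(sp, "14:0") == pytest.approx(0.5)
    plasm = parse_species_name("36:5e/pPE").with_chains(
        parse_chain_assignment("16:0p/20:4"))
    assert acyl_multiplicity(plasm, "16:0") == 1.0   # matches printed label
    cer = parse_species_name("34:1Cer").with_chains(
        parse_chain_assignment("d18:1/16:0"))
    assert acyl_multiplicity(cer, "18:1") == 0.0     # sphingoid base excluded
    assert acyl_multiplicity(cer, "16:0") == 1.0


def test_fractions_sum_to_one_with_determined_chains(sheet_8w, rng):
    cat = _mini_cat(("32:0PC", "16:0/16:0"), ("34:1PC", "16:0/18:1"),
                    ("36:2PC", "18:0/18:2"))
    samples = list(sheet_8w.index)
    norm = pd.DataFrame(rng.uniform(0.2, 5.0, size=(3, len(samples))),
                        index=cat.names, columns=samples)
    table = nl.sidechain_fraction_table(norm, cat, sheet_8w, "PC",
                                        (("HFD", 8), ("STAM", 8)))
    assert np.allclose(table.sum(axis=0), 1.0)
    assert table.loc["undetermined"].eq(0.0).all()


def test_undetermined_remainder_reported(sheet_8w):
    cat = _mini_cat(("34:1PC", "16:0/18:1"), ("38:3PC-b", "n.d."))
    norm = _uniform_table({"34:1PC": 1.0, "38:3PC-b": 1.0}, list(sheet_8w.index))
    table = nl.sidechain_fraction_table(norm, cat, sheet_8w, "PC",
                                        (("HFD", 8),))
    col = table.columns[0]
    determined = table.drop(index="undetermined")[col].sum()
    assert determined == pytest.approx(0.5)
    assert table.loc["undetermined", col] == pytest.approx(0.5)
    assert table[col].sum() == pytest.approx(1.0)


def test_fraction_against_chain_tally_oracle(panel, cat, sheet_8w):
    """Panel percentages as intensities: fractions equal a brute-force tally."""
    sub = panel[panel["class"] == "PC"]
    norm = pd.DataFrame({s: sub["pct_hfd"].to_numpy() for s in sheet_8w.index},
                        index=sub.index)
    for key in ("16:0", "18:0", "20:4"):
        got = nl.sidechain_fraction(norm, cat, sheet_8w, "PC", key, ("HFD", 8))
        # oracle: walk the chain strings and tally matches by hand
        numer = denom = 0.0
        for name, row in sub.iterrows():
            value = row["pct_hfd"]
            denom += 2 * value
            alts = [a.split("/") for a in row["chains"].split()
                    if row["chains"] != "n.d."]
            if alts:
                count = sum(sum(1 for tok in alt if tok.rstrip("ep") == key)
                            for alt in alts) / len(alts)
                numer += value * count
        assert got == pytest.approx(numer / denom)


def test_non_two_chain_class_rejected(sheet_8w, cat):
    norm = _uniform_table({"48:0TG": 1.0}, list(sheet_8w.index))
    with pytest.raises(ValueError, match="two-chain"):
        nl.sidechain_fraction(norm, cat, sheet_8w, "TG", "16:0", ("HFD", 8))


def test_substitution_effect_shifts_fraction_signs(cat, design):
    """Programmed 16:0 -> 18:0 substitution moves the fractions the right way."""
    hits = 0
    for seed in range(10):
        peak, sheet, _ = nl.generate_study(design, nl.PRESETS["sidechain8w"],
                                           cat, seed=seed)
        norm = nl.normalize_table(peak, cat)
        table = nl.sidechain_fraction_table(norm, cat, sheet, "PC",
                                            (("HFD", 8), ("STAM", 8)),
                                            fa_keys=("16:0", "18:0"))
        down = table.loc["16:0", "STAM-8w"] < table.loc["16:0", "HFD-8w"]
        up = table.loc["18:0", "STAM-8w"] > table.loc["18:0", "HFD-8w"]
        hits += down and up
    assert hits >= 9
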