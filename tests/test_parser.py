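"""Parsing: semantic decomposition, totality, hybrid detection."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gnkit.names import NameString, normalize
from gnkit.parser import detect_hybrid, parse, parse_string


class TestNormalization:
    def test_collapses_whitespace_and_trims(self):
        assert normalize("  Anthaenantia   villosa ") == "Anthaenantia villosa"

    def test_keeps_lookalike_codepoints_distinct(self):
        latin = normalize("Homo sapiens")
        cyrillic = normalize("Homo sаpiens")
        assert latin != cyrillic

    @given(st.text(max_size=80))
    def test_normalized_has_no_whitespace_runs(self, raw):
        norm = normalize(raw)
        assert norm == norm.strip()
        assert "  " not in norm


@pytest.mark.parametrize(
    "raw, genus, specific, infra, quality",
    [
        ("Bison bison athabascae", "Bison", "bison", [(None, "athabascae")], "clean"),
        (
            "Carex scirpoidea Michx. ssp. convoluta (Kük.) Dunlop",
            "Carex", "scirpoidea", [("ssp.", "convoluta")], "clean",
        ),
        ("Bison bison", "Bison", "bison", [], "clean"),
        (
            "Acer cappadocicum var. sinicum Rehder",
            "Acer", "cappadocicum", [("var.", "sinicum")], "clean",
        ),
    ],
)
def test_positional_rank_interpretation(raw, genus, specific, infra, quality):
    parsed = parse_string(raw)
    assert parsed.genus == genus
    assert parsed.specific_epithet == specific
    assert parsed.infraspecific_parts == infra
    assert parsed.quality == quality


def test_empty_input_is_unparseable():
    parsed = parse_string("")
    assert parsed.quality == "unparseable"
    assert parsed.genus is None and parsed.uninomial is None


def test_uninomial_with_surrogate_tail():
    parsed = parse_string("Characiformes sp. BOLD:AAC1024")
    assert parsed.uninomial == "Characiformes"
    assert any(a.kind == "sp_indet" for a in parsed.annotations)
    assert parsed.tail == "BOLD:AAC1024"
    assert parsed.quality == "with_tail"


def test_exactly_one_of_uninomial_genus_or_unparseable():
    for raw in ["Bison", "Bison bison", "ATCC 33224", "", "x Aranda"]:
        parsed = parse_string(raw)
        states = [
            parsed.uninomial is not None,
            parsed.genus is not None,
            parsed.quality == "unparseable",
        ]
        assert sum(states) == 1, raw


def test_infraspecific_implies_specific():
    parsed = parse_string("Cucumis melo subsp. melo var. conomon")
    assert parsed.specific_epithet == "melo"
    assert [m for m, _ in parsed.infraspecific_parts] == ["subsp.", "var."]


def test_combination_and_basionym_authorship():
    parsed = parse_string("Helicobacter pylori (Marshall et al. 1985) Goodwin et al. 1989")
    auth = parsed.authorship
    assert "Marshall" in auth.basionym_authors
    assert auth.basionym_year == 1985
    assert "Goodwin" in auth.combination_authors
    assert auth.combination_year == 1989


def test_bracketed_year_is_flagged():
    auth = parse_string("Athyma opalina (Kollar, [1844])").authorship
    assert auth.basionym_year == 1844
    assert auth.year_bracketed


def test_ex_authors_precede_publishing_authors():
    auth = parse_string("Oxalis adenophylla Gillies ex Hook. et Arn.").authorship
    assert auth.ex_authors == ["Gillies"]
    assert auth.combination_authors == ["Hook.", "Arn."]


def test_bracketed_genus_records_uncertainty_annotation():
    parsed = parse_string("[Bacillus] sp. KITNT-3")
    assert parsed.uninomial == "Bacillus"
    assert any(a.kind == "nom_status" and a.token == "[Bacillus]"
               for a in parsed.annotations)


def test_candidatus_prefix_sets_flag():
    parsed = parse_string("Candidatus Phytoplasma spartii Marcone et al. 2004")
    assert parsed.candidatus_flag
    assert parsed.genus == "Phytoplasma"


def test_lowercase_genus_recovery_is_flagged():
    parsed = parse_string("litoria ewingii")
    assert parsed.genus == "Litoria"
    assert parsed.case_repaired


def test_lowercase_recovery_does_not_promote_single_words():
    assert parse_string("bird").quality == "unparseable"
    assert parse_string("environmental samples").quality == "unparseable"


def test_subgenus_combination():
    parsed = parse_string("Lutzomyia (Helcocyrtomyia) hartmanni")
    assert parsed.genus == "Lutzomyia"
    assert parsed.subgenus == "Helcocyrtomyia"
    assert parsed.specific_epithet == "hartmanni"


def test_acronym_tail_is_never_mistaken_for_authorship():
    parsed = parse_string("Paludibacter propionicigenes CCUG 53888")
    assert parsed.authorship is None
    assert parsed.tail == "CCUG 53888"


def test_annotation_tokens_are_verbatim():
    parsed = parse_string("Gambierodiscus aff toxicus")
    tokens = [a.token for a in parsed.annotations]
    assert tokens == ["aff"]
    for token in tokens:
        assert token in "Gambierodiscus aff toxicus"


class TestHybridDetection:
    @pytest.mark.parametrize(
        "raw, flag, components",
        [
            (
                "Magnolia heptapeta x Magnolia quinquepeta",
                True, ["Magnolia heptapeta", "Magnolia quinquepeta"],
            ),
            ("x Cuprocyparis leylandii", True, ["Cuprocyparis leylandii"]),
            ("Bison bison", False, []),
            ("Malus x domestica", True, ["Malus domestica"]),
            (
                "Iris brevicaulis x fulva x hexagona",
                True, ["Iris brevicaulis", "Iris fulva", "Iris hexagona"],
            ),
        ],
    )
    def test_formula_components(self, raw, flag, components):
        assert detect_hybrid(NameString.of(raw)) == (flag, components)

    @pytest.mark.parametrize("sign", ["×", "х", "Х", "x", "X"])
    def test_all_sign_encodings_recognized(self, sign):
        raw = f"Magnolia heptapeta {sign} Magnolia quinquepeta"
        flag, components = detect_hybrid(NameString.of(raw))
        assert flag and len(components) == 2


class TestTotality:
    @given(st.text(max_size=120))
    def test_parse_never_raises(self, raw):
        parsed = parse(NameString.of(raw))
        assert parsed.quality in {"clean", "with_tail", "unparseable"}

    @given(st.text(max_size=120))
    def test_parse_is_deterministic(self, raw):
        name = NameString.of(raw)
        assert parse(name) == parse(name)

    def test_clean_quality_means_empty_tail(self):
        for raw in ["Bison bison", "Anolis barkeri Schmidt, 1939",
                    "Carex scirpoidea Michx. ssp. convoluta (Kük.) Dunlop"]:
            parsed = parse_string(raw)
            assert parsed.quality == "clean"
            assert parsed.tail == ""


def _collected_tokens(parsed, reference_tokens):
    """Reassemble the tokens a parse accounted for."""
    out = []
    annotation_tokens = [a.token for a in parsed.annotations]
    bracket = f"[{parsed.head}]" if parsed.head else None
    if parsed.head and bracket not in annotation_tokens \
            and parsed.head not in annotation_tokens:
        out.append(parsed.head)
    if parsed.subgenus:
        out.append(f"({parsed.subgenus})")
    if parsed.specific_epithet:
        out.append(parsed.specific_epithet)
    for marker, epithet in parsed.infraspecific_parts:
        if marker:
            out.append(marker)
        out.append(epithet)
    out.extend(t for t in annotation_tokens if t != "Candidatus" or True)
    if parsed.authorship:
        out.extend(parsed.authorship.verbatim.split())
    out.extend(parsed.tail.split())
    return out


@pytest.mark.parametrize(
    "raw",
    [
        "Bison bison athabascae",
        "Anolis barkeri POWELL & BIRT 2001",
        "Carex scirpoidea Michx. ssp. convoluta (Kük.) Dunlop",
        "Characiformes sp. BOLD:AAC1024",
        "Paludibacter propionicigenes CCUG 53888",
        "Lutzomyia (Helcocyrtomyia) hartmanni",
        "Gambierodiscus aff toxicus",
        "Candidatus Phytoplasma spartii Marcone et al. 2004",
        "Myxococcus Thaxter 1892 emend. Lang and Stackebrandt 2009",
        "Oleria onega n. ssp. ME-2007",
    ],
)
def test_token_conservation(raw):
    """Every non-whitespace token of the input lands in exactly one of:
    latinized components, authorship, annotations, or the tail."""
    name = NameString.of(raw)
    parsed = parse(name)
    got = sorted(_collected_tokens(parsed, name.normalized.split()))
    assert got == sorted(name.normalized.split())
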