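import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def anolis_variants():
    """Seven author/chresonym variants of one species name."""
    return [
        "Anolis barkeri",
        "Anolis barkeri (Schmidt, 1939)",
        "Anolis barkeri POWELL & BIRT 2001",
        "Anolis barkeri POWELL 2001",
        "Anolis barkeri Schmidt",
        "Anolis barkeri Schmidt 1939",
        "Anolis barkeri Schmidt, 1939",
    ]


@pytest.fixture(scope="session")
def paludibacter_variants():
    """Seven author/strain variants of one prokaryote name."""
    return [
        "Paludibacter propionicigenes",
        "Paludibacter propionicigenes Ueki et al. 2006",
        "Paludibacter propionicigenes CCUG 53888",
        "Paludibacter propionicigenes JCM 13257",
        "Paludibacter propionicigenes str. WB4",
        "Paludibacter propionicigenes WB4",
        "Paludibacter propionicigenes DSM 17365",
    ]


@pytest.fixture(scope="session")
def target_checklist():
    """A small target checklist exercising every match tier."""
    return [
        ("t1", "Pseudomonas syringae"),
        ("t2", "Acer cappadocicum var. sinicum Rehd."),
        ("t3", "Cnemidophorus tigris Baird & Girard, 1852"),
        ("t4", "Lysandra"),
        ("t5", "Cumia"),
        ("t6", "Mimia"),
        ("t7", "Mucia"),
        ("t8", "Mukia"),
        ("t9", "Numia"),
        ("t10", "Rumia"),
        ("t11", "Bison bison"),
        ("t12", "Ichneumon dorsalis"),
        ("t13", "Lasiodiplodia pseudotheobromae A.J.L. Phillips, A. Alves & Crous 2008"),
        ("t14", "Indigofera roseocaerulea Baker f"),
        ("t15", "Erigeron canadensis Brot."),
    ]


@pytest.fixture(scope="session")
def source_checklist():
    return [
        ("s1", "Pseudomonas syringae"),
        ("s2", "Acer cappadocicum subsp. sinicum (Rehder) Hand.-Mazz."),
        ("s3", "Cnemidophorus tigris aethiops"),
        ("s4", "Lysandra coridon gennargenti"),
        ("s5", "Mumia Lee et al. 2014"),
        ("s6", "chneumon dorsalis Fabricius, 1798"),
        ("s7", "Indigofera roseo-caerulea"),
        ("s8", "Lasidioplodia pseudobromae"),
        ("s9", "Erigeron canadensis L."),
        ("s10", "Nothing whatsoever"),
    ]
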