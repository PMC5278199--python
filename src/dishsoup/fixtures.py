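"""Built-in knowledge bases: the EGF signaling fragment and the vending machine.

The EGF fixture encodes the three printed reactions of the EGF-response
model — receptor activation (rule 001), Shp2 recruitment (rule 188) and
Hras nucleotide exchange (rule 529) — together with the initial state
EgfDish.  The published dish elides part of its contents ("and so forth"),
so this fixture is the minimal closure that supports the three-rule chain:
the named entities per location, with Gab1 and Sos1 present in the
tyrosine-phosphorylated state rule 529 requires (no rule of the fragment
phosphorylates them, and 529's own prerequisites demand those states).

The vending machine is the classic multiset-rewriting warm-up: a single
compartment holding money and products, with rules dollar -> four quarters,
dollar -> chocolate + quarter, and two quarters -> apple.
"""

from __future__ import annotations

from .kb import KnowledgeBase, Rule
from .sorts import SortHierarchy
from .terms import Complex, Dish, ElementVar, Entity, Modification, Soup

__all__ = [
    "egf_fixture",
    "vending_fixture",
    "EGF_RULE_CHAIN",
    "VENDING_DOLLAR_TO_QUARTERS",
    "VENDING_DOLLAR_TO_CHOCOLATE",
    "VENDING_QUARTERS_TO_APPLE",
]

YPHOS = Modification("Yphos")

EGF_RULE_CHAIN = ("001.EgfR.irt.Egf", "188.Shp2.irt.Egf", "529.Hras.irt.Egf")


def _e(name: str, *mods: Modification) -> Entity:
    return Entity(name, frozenset(mods))


def egf_fixture() -> KnowledgeBase:
    egfr_complex = Complex.of(_e("EgfR", YPHOS), _e("Egf"))

    rule_001 = Rule(
        label="001.EgfR.irt.Egf",
        lhs=Dish.of({"XOut": Soup.of(_e("Egf")), "EgfRC": Soup.of(_e("EgfR"))}),
        rhs=Dish.of({"XOut": Soup(), "EgfRC": Soup.of(egfr_complex)}),
        source="EGF outside the cell phosphorylates EgfR on tyrosine and binds it",
    )

    rule_188 = Rule(
        label="188.Shp2.irt.Egf",
        lhs=Dish.of(
            {
                "EgfRC": Soup.of(egfr_complex),
                "CLc": Soup.of(_e("Shp2")),
            }
        ),
        rhs=Dish.of(
            {
                "EgfRC": Soup.of(egfr_complex, _e("Shp2", YPHOS)),
                "CLc": Soup(),
            }
        ),
        source="Egf:EgfR-Yphos recruits Shp2 from the cytoplasm, phosphorylated",
    )

    gab = ElementVar("gab", "GabS", frozenset({YPHOS}))
    rasact = ElementVar("rasact", "RasActS", frozenset({YPHOS}))
    rule_529 = Rule(
        label="529.Hras.irt.Egf",
        lhs=Dish.of(
            {
                "EgfRC": Soup.of(egfr_complex, _e("Shp2", YPHOS)),
                "CLc": Soup.of(gab, rasact, _e("Pi3k")),
                "CLi": Soup.of(Complex.of(_e("Hras"), _e("GDP"))),
            }
        ),
        rhs=Dish.of(
            {
                "EgfRC": Soup.of(egfr_complex, _e("Shp2", YPHOS)),
                "CLc": Soup.of(gab, rasact, _e("Pi3k")),
                "CLi": Soup.of(Complex.of(_e("Hras"), _e("GTP"))),
            }
        ),
        source="with Gab and RasGrp3/Sos1 phosphorylated, Pi3k and Shp2-Yphos "
        "present, Hras switches its load from GDP to GTP",
    )

    egf_dish = Dish.of(
        {
            "XOut": Soup.of(_e("Egf")),
            "EgfRC": Soup.of(_e("EgfR")),
            "CLo": Soup(),
            "CLm": Soup.of(_e("Erbb2"), _e("Pag1"), _e("Plscr1")),
            "CLi": Soup.of(
                Complex.of(_e("Cdc42"), _e("GDP")),
                Complex.of(_e("Hras"), _e("GDP")),
                Complex.of(_e("Kras"), _e("GDP")),
                _e("Gnai1"),
                _e("Gnai3"),
                _e("Pld1"),
            ),
            "CLc": Soup.of(
                _e("Pi3k"),
                _e("Abl1"),
                _e("Akt1"),
                _e("Araf"),
                _e("ArhGap5"),
                _e("Shp2"),
                _e("Gab1", YPHOS),
                _e("Sos1", YPHOS),
            ),
            "NUc": Soup.of(_e("Atf1"), _e("Creb1"), _e("Elk1")),
        }
    )

    proteins = [
        "Egf", "EgfR", "Erbb2", "Pag1", "Plscr1", "Cdc42", "Hras", "Kras",
        "Gnai1", "Gnai3", "Pld1", "Pi3k", "Abl1", "Akt1", "Araf", "ArhGap5",
        "Shp2", "Atf1", "Creb1", "Elk1",
    ]
    entities: dict[str, list[str]] = {p: ["Protein"] for p in proteins}
    entities.update(
        {
            "Erks": ["ErkS"],
            "Gab1": ["GabS"],
            "Gab2": ["GabS"],
            "RasGrp3": ["RasActS"],
            "Sos1": ["RasActS"],
            "GDP": ["Chemical"],
            "GTP": ["Chemical"],
        }
    )
    sorts = SortHierarchy.build(
        {
            "Protein": set(),
            "ErkS": set(),
            "GabS": set(),
            "RasActS": set(),
            "Chemical": set(),
            "BProtein": {"Protein", "ErkS", "GabS", "RasActS"},
        },
        entities,
    )

    kb = KnowledgeBase(
        rules={r.label: r for r in (rule_001, rule_188, rule_529)},
        sorts=sorts,
        entities=entities,
        dishes={"EgfDish": egf_dish},
    )
    kb.validate()
    return kb


VENDING_DOLLAR_TO_QUARTERS = "vm1.dollar.to.quarters"
VENDING_DOLLAR_TO_CHOCOLATE = "vm2.dollar.to.chocolate.quarter"
VENDING_QUARTERS_TO_APPLE = "vm3.quarters.to.apple"

#: The single compartment of the vending machine.
VM = "VM"


def vending_fixture() -> KnowledgeBase:
    dollar, quarter, apple, chocolate = map(_e, ("dollar", "quarter", "apple", "chocolate"))

    rules = [
        Rule(
            label=VENDING_DOLLAR_TO_QUARTERS,
            lhs=Dish.of({VM: Soup.of(dollar)}),
            rhs=Dish.of({VM: Soup.of(quarter, quarter, quarter, quarter)}),
        ),
        Rule(
            label=VENDING_DOLLAR_TO_CHOCOLATE,
            lhs=Dish.of({VM: Soup.of(dollar)}),
            rhs=Dish.of({VM: Soup.of(chocolate, quarter)}),
        ),
        Rule(
            label=VENDING_QUARTERS_TO_APPLE,
            lhs=Dish.of({VM: Soup.of(quarter, quarter)}),
            rhs=Dish.of({VM: Soup.of(apple)}),
        ),
    ]
    entities = {n: ["Money"] for n in ("dollar", "quarter")}
    entities.update({n: ["Product"] for n in ("apple", "chocolate")})
    kb = KnowledgeBase(
        rules={r.label: r for r in rules},
        sorts=SortHierarchy.build({"Money": set(), "Product": set()}, entities),
        entities=entities,
        dishes={
            "DollarDish": Dish.of({VM: Soup.of(dollar)}),
            "TwoQuarterDish": Dish.of({VM: Soup.of(quarter, quarter)}),
        },
    )
    kb.validate()
    return kb
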