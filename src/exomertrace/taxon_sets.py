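"""Named annotation-label sets for the fungal ChAP divergence battery.

These are the standard taxon sets used when comparing the duplicated
paralogue clades (BB8 = Bch1 + Bud7, BC8 = Bch2 + Chs6) against their
preduplicate relatives: per-paralogue sets, preduplicate sets, the
non-ascomycete ChAP outgroup, the pooled clade sets, and the
genus-balanced sets keeping a single ascomycete genus (S. cerevisiae).

Labels follow the family-prefix + genus-tag convention (e.g. ``Bud7Scer``
is the S. cerevisiae Bud7 sequence, ``ChAPYlip`` the Y. lipolytica
preduplicate ChAP).
"""

from __future__ import annotations

from .divergence import TaxonSet, balance_by_genus

BUD7 = TaxonSet.of("Bud7", [
    "Bud7Spar", "Bud7Scer", "Bud7Sbou", "Bud7Sbay", "Bud7Seub", "Bud7Sarb",
])
BCH1 = TaxonSet.of("Bch1", [
    "Bch1Sbay", "Bch1Seub", "Bch1Skud", "Bch1Sarb", "Bch1Spar", "Bch1Scer",
    "Bch1Sbou",
])
BCH2 = TaxonSet.of("Bch2", [
    "Bch2Scer", "Bch2Sbou", "Bch2Spar", "Bch2Skud", "Bch2Sarb", "Bch2Sbay",
    "Bch2Seub",
])
CHS6 = TaxonSet.of("Chs6", [
    "Chs6Sbay", "Chs6Seub", "Chs6Sarb", "Chs6Skud", "Chs6Smik", "Chs6Scer",
    "Chs6Sbou", "Chs6Spar",
])
PDBB8 = TaxonSet.of("PDBB8", [
    "BB8Ppas", "BB8Calb", "BB8Dhan", "BB8Psti", "BB8Klac", "BB8Ago",
])
PDBC8 = TaxonSet.of("PDBC8", [
    "BC8Klac", "BC8Cgla", "BC8Agos", "BC8Psti", "BC8Ppas", "BC8Calb",
    "BC8Dhan",
])
CHAP = TaxonSet.of("ChAP", [
    "ChAPYlip", "ChAPNcra", "ChAPAmac", "ChAPBden", "ChAPSpom", "ChAPCneo",
    "ChAPUmay", "ChAPMver", "ChAPRirr", "ChAPRory",
])

BB8_ALL = TaxonSet.of("BB8All", sorted(BUD7.members | BCH1.members | PDBB8.members))
BC8_ALL = TaxonSet.of("BC8All", sorted(BCH2.members | CHS6.members | PDBC8.members))

#: duplicated-clade members (subject to genus balancing; preduplicates are not)
BB8_DUPLICATED = frozenset(BUD7.members | BCH1.members)
BC8_DUPLICATED = frozenset(BCH2.members | CHS6.members)

BB8_B = TaxonSet(
    "BB8-B", balance_by_genus(BB8_ALL, "Scer", BB8_DUPLICATED).members
)
BC8_B = TaxonSet(
    "BC8-B", balance_by_genus(BC8_ALL, "Scer", BC8_DUPLICATED).members
)

ALL_SETS = {
    s.name: s
    for s in (BUD7, BCH1, BCH2, CHS6, PDBB8, PDBC8, CHAP, BB8_ALL, BC8_ALL,
              BB8_B, BC8_B)
}
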