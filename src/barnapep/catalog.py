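"""Synthetic neuropeptidome catalog for the barnacle study system.

The study's published precursor tables give only a handful of exact
sequences and a set of hard counts; the raw precursor set itself is not
machine-readable.  This module therefore carries a SYNTHETIC reconstruction
of that catalog: 17 precursors covering the 16 neuropeptide
families/subfamilies, built so that every printed constraint holds when the
package's own processing rules are applied:

* 64 mature peptides in total across the catalog;
* the PDH mature peptide is NSELINSLLGLPKIMNEAamide and the ASTC mature
  peptide SYWKQCSFNAVSCFamide;
* the B-type allatostatin precursor carries 10 peptide isoforms and the
  tachykinin-related-peptide precursor 4 copies;
* mature orcokinin is 14 residues long;
* sulfakinins 2-4 carry Lys8 and Met6/Phe6 variants of the canonical
  [YF]G[HMF][MLF][RK]Famide core, with an acidic (sulfated) Tyr;
* A-type allatostatins comprise 9 distinct FGLamide isoforms present in
  multiple copies.

All other sequence content (the large hormones, spacer-free precursor
architecture, copy numbers not pinned by the counts above) is invented and
should be treated as synthetic fixture data, not biology.  Calcitonin-like
diuretic hormone isoforms A and B sit on separate precursors but share the
single family CALCI, which is how 17 precursors count as 16 families.
"""

from __future__ import annotations

from .simulate import Payload, PrecursorSpec, generate_precursor, PlantedPrecursor

# family -> list of (sequence, amidate, copies)
_CATALOG_PAYLOADS: dict[str, list[tuple[str, bool, int]]] = {
    "ASTA": [
        ("AGPYSFGL", True, 4),
        ("ASPYAFGL", True, 3),
        ("GGPYSFGL", True, 3),
        ("APQPYSFGL", True, 3),
        ("SAGPYNFGL", True, 3),
        ("GDPYAFGL", True, 3),
        ("AGQYTFGL", True, 3),
        ("DPMYGFGL", True, 2),
        ("SGNYNFGI", True, 2),
    ],
    "ASTB": [
        ("AWQDLNSAW", True, 1),
        ("AWSDLNSAW", True, 1),
        ("GWQDLNSVW", True, 1),
        ("AWSNMNTAW", True, 1),
        ("NWNQLNAGW", True, 1),
        ("AWSSMNTAW", True, 1),
        ("TWNELNSAW", True, 1),
        ("AWQNMNSAW", True, 1),
        ("SWDQLNGAW", True, 1),
        ("EPAWNSLNSAW", True, 1),
    ],
    "ASTC": [("SYWKQCSFNAVSCF", True, 1)],
    "BURSA": [(
        "DECSLTPVIHFLSYPGCSSKAYPTEACQGSCTSDVQVSGSKLWQDMSECNCQPGVSEYQSVT"
        "LQCPGEDNHMTKVFTYPVASSCQCSMCNSN", False, 1)],
    "BURSB": [(
        "EGDECQVTPVIHVLQYPGCVPKPIPSFACQGACTSYVQVSGSKIWQTEACAECTPSQSEAVT"
        "VPLHCPKAESSEPDILVYPVACECSQCSTDHTH", False, 1)],
    "CALCIA": [("GLDLGLSKGFSGSQEAKHLMGLAAANYAGGP", True, 1)],
    "CALCIB": [("ALDLGLSKGVSGAQEAKHFMGLAAANFAGGP", True, 1)],
    "CLDH": [("SGELDSSMNSLLEAYQAMQEAENAELSHNVSEELKASFDNFNQ", False, 1)],
    "EH": [(
        "NPAIATGYDPMEICIENCAQCKKMFGPWFEGSLCAESCIKTQGKDIPECESFASIAPFLNKLE",
        False, 1)],
    "IRP": [
        ("GVDQECWSHVCSYSELTALC", False, 1),      # B chain
        ("SADLESNMALDSPFEKQMSGELAGE", False, 1),  # C peptide
        ("GIVDECCNKPCTLSELSSYCA", False, 1),      # A chain
    ],
    "ITP": [(
        "SFFDIQCKGVYDKSIFAKLDHICEDCYNLFHEPHLHSLCHKDCFTSDYFKGCLDVLLLQDEM"
        "DKIQSWIKQL", True, 1)],
    "NPF": [("SMVDPNKLFEFPNELAQYLNQLSDYYALAGDTSNPTRQRF", True, 1)],
    "ORCO": [
        ("NFDEIDRSGFGFAV", False, 2),
        ("NFDEIDRSSFGFAV", False, 2),
        ("NFDEIDRTGFGFAV", False, 2),
    ],
    "PDH": [("NSELINSLLGLPKIMNEA", True, 1)],
    "SIF": [("GYRKPTFNGSIF", True, 1)],
    "SULF": [
        ("QFDDYGHMRF", True, 1),
        ("AADEYGFMKF", True, 1),
        ("GGEEYGMLKF", True, 1),
        ("SLDDYGFFKF", True, 1),
    ],
    "TRP": [
        ("APSGFLGMR", True, 1),
        ("APSGFFGMR", True, 1),
        ("SSSGFLGMR", True, 1),
        ("APQGFYGVR", True, 1),
    ],
}

#: precursor id -> family label used for homology/reporting; the two
#: calcitonin isoform precursors share the CALCI family.
PRECURSOR_FAMILY = {name: ("CALCI" if name.startswith("CALCI") else name)
                    for name in _CATALOG_PAYLOADS}

_SEED_BASE = 20121002  # fixed: the catalog is a deterministic fixture


def catalog_specs() -> dict[str, PrecursorSpec]:
    """One spacer-free PrecursorSpec per catalog precursor (17 in total)."""
    specs = {}
    for name, payloads in _CATALOG_PAYLOADS.items():
        expanded = []
        for seq, amidate, copies in payloads:
            expanded.extend([Payload(seq, amidate)] * copies)
        specs[name] = PrecursorSpec(
            family=PRECURSOR_FAMILY[name], payloads=tuple(expanded),
        )
    return specs


def catalog_precursors() -> dict[str, tuple[str, PlantedPrecursor]]:
    """Deterministic (protein, ground truth) for each catalog precursor."""
    out = {}
    for i, (name, spec) in enumerate(sorted(catalog_specs().items())):
        out[name] = generate_precursor(spec, _SEED_BASE + i)
    return out


def discovery_specs(max_payloads: int = 12,
                    spacer_len: int = 10) -> list[PrecursorSpec]:
    """One screen-compliant precursor per family (16 specs).

    Each spec carries a leading propeptide spacer (so even single-peptide
    precursors have a processing site) and at most ``max_payloads`` peptide
    instances, keeping every precursor under the 300-residue screen.  For
    the CALCI family the isoform-A precursor is used.
    """
    specs = []
    for name, payloads in _CATALOG_PAYLOADS.items():
        if name == "CALCIB":
            continue
        expanded = []
        for seq, amidate, copies in payloads:
            expanded.extend([Payload(seq, amidate)] * copies)
        expanded = expanded[:max_payloads]
        specs.append(PrecursorSpec(
            family=PRECURSOR_FAMILY[name], payloads=tuple(expanded),
            spacer_len=spacer_len,
        ))
    return specs
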