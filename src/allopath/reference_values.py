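"""Published binding-energy component means for the Ras–SOS systems.

These are the reported MM/PBSA component means (kcal/mol) for the
K-Ras4B(G13D)·SOScat binary complex and the ternary complex with a second,
allosteric K-Ras4B(G13D)–GTP bound, as printed in the literature.  They are
*inputs* to the arithmetic consistency checker
(:func:`allopath.energetics.verify_table2_consistency`): the package
recomputes the derived rows (ΔE_MM, ΔG_solv, ΔG_binding) from the printed
components through the end-state bookkeeping identities and reports
discrepancies — including the sign inconsistency of the binary polar
component, which is compatible with the printed ΔG_binding only as
+163.28 kcal/mol.
"""

from __future__ import annotations

#: printed component means, kcal/mol (SDs omitted; not needed for bookkeeping)
PUBLISHED_BINDING_COMPONENTS: dict[str, dict[str, float]] = {
    "binary": {
        "dE_vdW": -138.73,
        "dE_ele": -154.08,
        "dE_polar": -163.28,
        "dE_nonpolar": -17.00,
        "dE_MM": -292.82,
        "dG_solv": -146.29,
        "dG_binding": -146.53,
    },
    "ternary": {
        "dE_vdW": -159.66,
        "dE_ele": -106.65,
        "dE_polar": 128.48,
        "dE_nonpolar": -18.39,
        "dE_MM": -266.31,
        "dG_solv": 110.09,
        "dG_binding": -156.22,
    },
}

#: binding free energies as quoted in the accompanying text (kcal/mol);
#: the binary value differs from the tabulated one by a 0.01 rounding step
PUBLISHED_BINDING_TEXT: dict[str, float] = {"binary": -146.54, "ternary": -156.22}

#: reported strengthening of the catalytic-site interaction on allosteric
#: Ras–GTP binding: |ΔG_ternary − ΔG_binary| from the text values
PUBLISHED_BINDING_SHIFT: float = 9.68
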