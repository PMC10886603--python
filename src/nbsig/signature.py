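"""The published neuroblastoma signature: gene lists and model-feature bookkeeping.

Thirty-five genes survive intersection across the three cohorts; nineteen of
them pass the univariate EFS screen at the Bonferroni threshold; B3GAT1
(isoform ambiguity) and FRAS1 (non-significant KM association) are excluded,
leaving the seventeen-gene signature.  Adding the three clinical prognostic
features (MYCN amplification, diagnosis before 18 months, INSS stage) gives
the twenty model features.  Gene aliases are normalised to a single symbol
(BSG for BSG/CD147, GNB2L1 for GNB2L1/RACK1).
"""

from __future__ import annotations

#: Genes present in all three cohorts (n = 35).
COMMON_GENES = (
    "B3GAT1", "BASP1", "BSG", "CCDC125", "CD9", "CEBPD", "CNKSR3", "COL18A1",
    "COL5A1", "CYP3A5", "DLG2", "DUOX1", "EFNA2", "FLVCR1", "FNBP1", "FRAS1",
    "FRMD3", "FRMD6", "GABRB3", "GNB2L1", "HAPLN4", "HEBP2", "HSD17B12",
    "HSPA2", "IGSF10", "IL11RA", "IL4R", "INPP5F", "IQCE", "ISG15", "ITGA11",
    "ITGB5", "KCNQ3", "NEK6", "TOX2",
)

#: Genes individually predictive of EFS at the Bonferroni threshold (n = 19).
SCREENED_GENES = (
    "B3GAT1", "BASP1", "BSG", "CCDC125", "CD9", "DLG2", "FNBP1", "FRAS1",
    "FRMD3", "GABRB3", "GNB2L1", "HAPLN4", "HEBP2", "HSD17B12", "IGSF10",
    "IL11RA", "IQCE", "KCNQ3", "TOX2",
)

#: Excluded after the screen: B3GAT1 (isoform/CD57 ambiguity), FRAS1
#: (non-significant KM association).
EXCLUDED_GENES = ("B3GAT1", "FRAS1")

#: The seventeen-gene prognostic signature.
SIGNATURE_GENES = tuple(g for g in SCREENED_GENES if g not in EXCLUDED_GENES)

#: Clinical prognostic features added to the model.
CLINICAL_FEATURES = ("mycn_amplified", "age_lt_18_months", "inss_stage")

#: Signature genes whose *high* expression tracks favourable EFS.
FAVOURABLE_HIGH = (
    "BASP1", "CD9", "DLG2", "FNBP1", "FRMD3", "IL11RA", "IGSF10", "IQCE",
    "KCNQ3", "TOX2",
)

#: Signature genes whose *low* expression tracks favourable EFS.
FAVOURABLE_LOW = ("BSG", "CCDC125", "GABRB3", "GNB2L1", "HAPLN4", "HEBP2", "HSD17B12")


def assemble_model_features(
    screened: tuple[str, ...] = SCREENED_GENES,
    excluded: tuple[str, ...] = EXCLUDED_GENES,
    clinical: tuple[str, ...] = CLINICAL_FEATURES,
) -> list[str]:
    """Signature bookkeeping: screened genes minus exclusions plus clinical features."""
    genes = [g for g in screened if g not in set(excluded)]
    return genes + list(clinical)
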