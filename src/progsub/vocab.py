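"""Built-in demo code vocabulary and mapping-table loading.

Real deployments map tens of thousands of ICD-9/10-CM codes to ~1,800
Phecodes and drug codes (NDC/RxNorm) to ATC level 3.  Shipping the licensed
full maps is out of scope; this module provides (a) a small demo vocabulary
sufficient for the synthetic cohort and the examples, and (b) a loader for
user-supplied two-column mapping files covering the full vocabularies.

The cohort-defining code sets (MCI and AD diagnosis codes, ICD-9/10-CM) are
the standard computable-phenotype lists for the Alzheimer's continuum and
are used both to place stage-onset diagnoses in synthetic records and to
re-derive stage dates when reading raw tables.
"""

from __future__ import annotations

# ICD codes defining cognitive-stage onset on the AD continuum.
MCI_CODES = frozenset(
    {"331.83", "294.9", "G31.84", "F06.7", "F09", "R41.840", "R41.841", "R41.89", "R41.9"}
)
AD_CODES = frozenset({"331.0", "G30", "G30.0", "G30.1", "G30.8", "G30.9"})

# Demo ICD -> Phecode rollup.  Phecode strings follow the usual
# "<number> <label>" style used in PheWAS catalogs (labels abbreviated).
DEMO_ICD_TO_PHECODE: dict[str, str] = {
    # stage-defining codes
    **{c: "290.1 MCI" for c in MCI_CODES},
    **{c: "290.11 AD" for c in AD_CODES},
    # circulatory
    "I10": "401.1 Essential hypertension",
    "401.9": "401.1 Essential hypertension",
    "I48.91": "427.2 Atrial fibrillation",
    "427.31": "427.2 Atrial fibrillation",
    "I25.10": "411.4 Coronary atherosclerosis",
    "414.01": "411.4 Coronary atherosclerosis",
    "I50.9": "428.2 Heart failure",
    # endocrine / metabolic
    "E78.5": "272.1 Hyperlipidemia",
    "272.4": "272.1 Hyperlipidemia",
    "E11.9": "250.2 Type 2 diabetes",
    "250.00": "250.2 Type 2 diabetes",
    "E03.9": "244.4 Hypothyroidism",
    # musculoskeletal
    "M19.90": "740.1 Osteoarthrosis",
    "715.90": "740.1 Osteoarthrosis",
    "M54.5": "760.0 Back pain",
    "724.2": "760.0 Back pain",
    "M81.0": "743.1 Osteoporosis",
    # genitourinary
    "N39.0": "591.0 Urinary tract infection",
    "599.0": "591.0 Urinary tract infection",
    # hematopoietic
    "D64.9": "285.0 Anemia",
    "285.9": "285.0 Anemia",
    # mental / neurological
    "F32.9": "296.22 Major depressive disorder",
    "311": "296.22 Major depressive disorder",
    "F41.9": "300.1 Anxiety disorder",
    "G47.00": "327.4 Insomnia",
    "R53.83": "798.1 Malaise and fatigue",
    "780.79": "798.1 Malaise and fatigue",
    # digestive
    "K21.9": "530.11 GERD",
    "530.81": "530.11 GERD",
    "K59.00": "563.0 Constipation",
    # sensory
    "H25.9": "366.0 Cataract",
    "366.9": "366.0 Cataract",
    # neoplasm
    "C61": "185.0 Prostate cancer",
    "D49.9": "199.0 Neoplasm unspecified",
}

# Demo drug code -> ATC level 3 rollup (codes are RxNorm-flavoured ids).
DEMO_DRUG_TO_ATC3: dict[str, str] = {
    "rx:donepezil": "N06D Anti-dementia drugs",
    "rx:memantine": "N06D Anti-dementia drugs",
    "rx:lisinopril": "C09A ACE inhibitors",
    "rx:losartan": "C09C ARBs",
    "rx:amlodipine": "C08C Calcium channel blockers",
    "rx:metoprolol": "C07A Beta blockers",
    "rx:atorvastatin": "C10A Lipid modifying agents",
    "rx:simvastatin": "C10A Lipid modifying agents",
    "rx:metformin": "A10B Blood glucose lowering",
    "rx:levothyroxine": "H03A Thyroid preparations",
    "rx:sertraline": "N06A Antidepressants",
    "rx:escitalopram": "N06A Antidepressants",
    "rx:omeprazole": "A02B Drugs for peptic ulcer",
    "rx:ibuprofen": "M01A Antiinflammatory",
    "rx:alendronate": "M05B Bone structure drugs",
    "rx:nitrofurantoin": "J01X Other antibacterials",
}


class MappingError(ValueError):
    """Raised when a user-supplied mapping file cannot be parsed."""


def load_mapping_table(path) -> dict[str, str]:
    """Load a two-column delimited mapping file (source_code,target_code).

    Lines starting with '#' and a first line equal to the canonical header
    are skipped.  Malformed lines raise :class:`MappingError` naming the
    line number.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().replace(" ", "") in (
                "source,target",
                "source_code,target_code",
            ):
                continue
            parts = line.split(",")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise MappingError(f"{path}: malformed mapping at line {lineno}: {raw!r}")
            mapping[parts[0].strip()] = parts[1].strip()
    return mapping
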