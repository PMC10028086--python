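"""Bundled example data.

``load_pathogenic_calls`` returns the curated table of pathogenic CNVs
reported in a published 212-patient neurodevelopmental-disorder cohort
(27 calls in 26 patients; one patient carries a double terminal deletion).
The module-level constants record the cohort composition and the post-filter
call-class totals reported alongside that table; together they let the worked
examples (diagnostic yield, sex burden, class shares, interval sizes) be
recomputed from printed inputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .intervals import GenomicInterval
from .io_formats import CnvCall, VariantType

__all__ = [
    "COHORT_SIZE", "N_MALE", "N_FEMALE",
    "CALLS_TOTAL", "CALLS_PATHOGENIC", "CALLS_VOUS",
    "PathogenicRecord", "load_pathogenic_calls",
]

COHORT_SIZE = 212
N_MALE = 145
N_FEMALE = 67

# post-filter call-class totals reported with the cohort
CALLS_TOTAL = 1581
CALLS_PATHOGENIC = 27
CALLS_VOUS = 214


@dataclass(frozen=True)
class PathogenicRecord:
    call: CnvCall
    sex: str
    band: str


def load_pathogenic_calls() -> list[PathogenicRecord]:
    ref = resources.files("cnvland.data").joinpath("ndd_cohort_pathogenic_cnvs.tsv")
    records: list[PathogenicRecord] = []
    with ref.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                PathogenicRecord(
                    call=CnvCall(
                        sample_id=row["patient_id"],
                        interval=GenomicInterval(
                            row["chrom"], int(row["start"]), int(row["end"])
                        ),
                        vtype=VariantType(row["type"]),
                    ),
                    sex=row["sex"],
                    band=row["band"],
                )
            )
    return records
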