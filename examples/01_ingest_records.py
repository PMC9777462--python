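"""Ingesting long-format lab records into a case × analyte matrix.

Builds a six-row lab export, pivots it into a matrix with a missingness
mask, derives binary diagnosis labels from ICD-10 code lists, and applies
the measured-troponin cohort filter.
"""

import tempfile
from pathlib import Path

from labsieve import build_matrix, filter_troponin_cohort, label_cases, parse_records

RECORDS = """case_id\tanalyte_id\tanalyte_name\tvalue\tunit\ttimestamp
p1\ttnt\tTroponin T\t12.5\tng/L\t1
p1\tk\tPotassium\t4.2\tmmol/L\t1
p2\ttnt\tTroponin T\t240\tng/L\t1
p2\ttnt\tTroponin T\t310\tng/L\t7
p2\tcoll\tType of blood collection\tarterial\t\t1
p3\tk\tPotassium\t3.9\tmmol/L\t1
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "records.tsv"
    path.write_text(RECORDS)
    records = parse_records(path)

matrix = build_matrix(records)  # duplicate TnT for p2 -> earliest kept (240)
labels = label_cases({"p1": ["E11.9"], "p2": ["I21.4", "J18.9"], "p3": ["I25.90"]})
cohort, cohort_labels = filter_troponin_cohort(matrix, labels, "tnt")

print("full matrix (NaN = not measured):")
print(matrix.to_frame())
print("\nlabels (1 = ICD-10 code in I20-I25):", labels.labels)
print("troponin-measured cohort:", cohort.cases)
print("collection-type encoding:", matrix.encoding_map["coll"])
# p3 is dropped: no measured troponin means the patient was never worked up
# for myocardial ischemia, so it is outside the differential-diagnosis cohort.
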