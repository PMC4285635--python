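"""Cohort phenology bookkeeping: stages, molt phases, durations.

Builds a small staged cohort and derives the daily composition table,
percentages, and the median stage duration.
"""

from moltmark import (
    CohortRecord,
    classify_apolysis,
    daily_composition,
    median_stage_duration,
    proportion,
)

records = []
# day 6: mostly pre-apolysis; day 10: mostly post-apolysis, adults appear
for k in range(8):
    records.append(CohortRecord(f"d6_{k}", 6, "C5",
                                jaw_phase="interphase" if k < 6 else "apolysis"))
for k in range(6):
    records.append(CohortRecord(f"d10_{k}", 10, "C5",
                                jaw_phase="silicified-teeth" if k < 4 else "columnar-cell"))
records += [CohortRecord(f"d10_a{k}", 10, "adult", molt_day=0.0, adult_day=10.0)
            for k in range(2)]
records += [CohortRecord(f"dur_{k}", 14, "adult", molt_day=0.0, adult_day=d)
            for k, d in enumerate((13.0, 14.0))]

print("jaw phase 'interphase' ->", classify_apolysis("interphase"))
print("jaw phase 'silicified-teeth' ->", classify_apolysis("silicified-teeth"))
print("proportion(44, 173) ->", proportion(44, 173), "% males among emerged adults")

comp = daily_composition(records)
print("\ndaily composition:")
print(comp[["n", "pct_C5", "pct_adult", "pct_post_apolysis"]].fillna("-").to_string())

print(f"\nmedian stage duration: {median_stage_duration(records):g} days")
# The post-apolysis percentage rises from 25% on day 6 to 67% on day 10,
# and completed molt-to-molt intervals give the median C5 stage duration.
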