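"""Map lengths of stay onto satisfaction scores.

Shows the triangular moments behind each patient type's mapping and the score
a few representative stays receive: the score is the mean elicited score
shifted by the standardized LOS deviation, clamped to [0, 100], and never
increases with a longer stay.
"""

from hospflow import ScoreMapping, los_to_score
from hospflow.satisfaction import DEFAULT_PROFILES, tri_mean, tri_sd

for ptype, profile in DEFAULT_PROFILES.items():
    mapping = ScoreMapping.from_profile(profile)
    print(
        f"type {ptype}: LOS mean {mapping.mean_los:6.2f} min (sd {mapping.sd_los:5.2f}), "
        f"score mean {mapping.mean_score:5.1f}% (sd {mapping.sd_score:5.2f})"
    )
    for los in (profile.los_tri.optimistic, tri_mean(profile.los_tri),
                profile.los_tri.pessimistic, 3 * profile.los_tri.pessimistic):
        print(f"    LOS {los:6.1f} min -> score {los_to_score(mapping, los):6.2f}%")

print(
    "\nThe optimistic stay scores near (or at) 100%, the mean stay maps to "
    "the mean elicited score (75%), and extreme stays clamp to 0%."
)
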