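"""Published summary counts for the national cohort being emulated.

These are the reported patient and test-event counts from the national
public-sector laboratory cohort whose structure the synthetic generator
mimics (373,889 adults with a first diabetes-type laboratory test
between January 2012 and March 2015). They are inputs, not outputs: the
package uses them to recompute the crude-proportion arithmetic of the
published tables (numerator / denominator -> percentage) and as the
yardstick the simulator's default marginals were set against. None of
these numbers is produced by this package's computations on real data —
the underlying cohort is not publicly available.
"""

from __future__ import annotations

# Patient-level counts in the national cohort.
N_TESTED = 373_889
N_DIAGNOSED = 186_664
N_FEMALE = 237_426
N_HOSPITAL = 231_909
N_PLWOH = 317_160
N_TB_NEGATIVE = 368_423

# One province's diagnosed count over its tested denominator.
N_GP_TESTED = 118_194
N_GP_DIAGNOSED = 55_086

# Test-event counts (a patient can contribute several events).
N_EVENTS_TOTAL = 1_562_255
N_EVENTS_HBA1C = 1_063_137
N_EVENTS_HOSPITAL = 825_272
N_EVENTS_GLUCOSE_DENOM = 707_721
N_EVENTS_GLUCOSE_CLINIC = 136_257

# Retention under the two definitions among the diagnosed.
N_RETAINED_ANY = 92_638
N_RETAINED_DM = 60_624


def crude_percentages() -> dict:
    """Recompute every crude percentage from its numerator/denominator.

    Returns percentages on the 0-100 scale, rounded to one decimal
    (event shares to the nearest percent, matching how they were
    reported), plus the any-lab minus diabetes-lab retention count
    difference.
    """
    return {
        "diagnosed_pct": round(100 * N_DIAGNOSED / N_TESTED, 1),
        "female_pct": round(100 * N_FEMALE / N_TESTED, 1),
        "hospital_pct": round(100 * N_HOSPITAL / N_TESTED, 1),
        "plwoh_pct": round(100 * N_PLWOH / N_TESTED, 1),
        "tb_negative_pct": round(100 * N_TB_NEGATIVE / N_TESTED, 1),
        "gp_diagnosed_pct": round(100 * N_GP_DIAGNOSED / N_GP_TESTED, 1),
        "hba1c_event_share_pct": round(100 * N_EVENTS_HBA1C / N_EVENTS_TOTAL),
        "hospital_event_share_pct": round(100 * N_EVENTS_HOSPITAL / N_EVENTS_TOTAL),
        "clinic_glucose_share_pct": round(
            100 * N_EVENTS_GLUCOSE_CLINIC / N_EVENTS_GLUCOSE_DENOM),
        "retention_definition_gap": N_RETAINED_ANY - N_RETAINED_DM,
    }
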