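"""The nine coding categories used to label media comments.

Comments on violence-against-doctors news reports are coded into nine
attitude categories (blame/support directed at the big system, the medical
system, the doctor, the patient, or other targets, plus an N/A bucket for
off-case comments).  For the policy analysis two merged outcomes are used:
"support doctor" pools Support Doctor with Blame Patient, and "blame
doctor" pools Blame Doctor with Support Patient, since each pair expresses
the same side of the doctor-patient conflict.
"""

from __future__ import annotations

BLAME_BIG_SYSTEM = "Blame Big System"
BLAME_MEDICAL_SYSTEM = "Blame Medical System"
BLAME_DOCTOR = "Blame Doctor"
BLAME_PATIENT = "Blame Patient"
BLAME_OTHER = "Blame Other"
SUPPORT_DOCTOR = "Support Doctor"
SUPPORT_PATIENT = "Support Patient"
SUPPORT_OTHER = "Support Other"
NA = "N/A"

CATEGORIES: tuple[str, ...] = (
    BLAME_BIG_SYSTEM,
    BLAME_MEDICAL_SYSTEM,
    BLAME_DOCTOR,
    BLAME_PATIENT,
    BLAME_OTHER,
    SUPPORT_DOCTOR,
    SUPPORT_PATIENT,
    SUPPORT_OTHER,
    NA,
)

CATEGORY_INDEX: dict[str, int] = {c: i for i, c in enumerate(CATEGORIES)}

# Merged outcomes for the interrupted time series analysis.
SUPPORT_GROUP = frozenset({SUPPORT_DOCTOR, BLAME_PATIENT})
BLAME_GROUP = frozenset({BLAME_DOCTOR, SUPPORT_PATIENT})
OTHER_GROUP = frozenset(CATEGORIES) - SUPPORT_GROUP - BLAME_GROUP

SUPPORT_TAG = "support_doctor"
BLAME_TAG = "blame_doctor"
OTHER_TAG = "other"


def validate_labels(labels) -> frozenset[str]:
    """Validate a label set: known categories, non-empty, N/A exclusive."""
    labels = frozenset(labels)
    unknown = labels - set(CATEGORIES)
    if unknown:
        raise ValueError(
            f"unknown categories {sorted(unknown)}; valid names are {list(CATEGORIES)}"
        )
    if not labels:
        raise ValueError("label set must be non-empty")
    if NA in labels and len(labels) > 1:
        raise ValueError("N/A is exclusive and cannot co-occur with other labels")
    return labels
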