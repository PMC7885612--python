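# Canonical clinical-note section names and surface variants.
# Format: CANONICAL NAME | variant | variant ...
# Matching is case-insensitive on "<header>:" at a line-ish boundary.
CLINICAL HISTORY
HISTORY OF PRESENT ILLNESS | HPI
PAST MEDICAL HISTORY | PMH
ALLERGIES
FAMILY HISTORY
SOCIAL HISTORY
CHIEF COMPLAINT | CC
MAJOR SURGICAL OR INVASIVE PROCEDURE | MAJOR SURGICAL PROCEDURE
SERVICE
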