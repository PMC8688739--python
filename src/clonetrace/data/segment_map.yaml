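# Explicit segment-label overrides applied before pattern-based normalisation.
# Keys are verbatim labels as they appear in clone tables; values are the
# family-level tokens used throughout the package.  Extend this table for
# platform-specific oddities that the TCRB[VDJ]nn-mm pattern cannot resolve.
TCRBDX: D-unresolved
TCRBDX-01: D-unresolved
unresolved: D-unresolved
# Adaptive reports ambiguous V orphons with an "-or" infix; keep family level.
TCRBV12-or09_02: V12
TCRBV06-or05_05: V6
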