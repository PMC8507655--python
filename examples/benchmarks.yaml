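# Illustrative cancer-risk benchmark table.
#
# benchmark = concentration corresponding to 10^-6 lifetime cancer risk,
# in the stated unit. These numbers are EXAMPLES for exercising the
# pipeline, not authoritative regulatory or health-guideline values:
# real analyses must supply their own vetted table.
contaminants:
  - {id: THM4, benchmark: 0.15, unit: "µg/L", group: DBP}
  - {id: HAA5, benchmark: 0.10, unit: "µg/L", group: DBP}
  - {id: HAA9, benchmark: 0.06, unit: "µg/L", group: DBP}
  - {id: ARSENIC, benchmark: 0.004, unit: "µg/L"}
  - {id: NITRATE, benchmark: 0.14, unit: "mg/L"}
  - {id: RADIUM, benchmark: 0.05, unit: "pCi/L"}
group_rules:
  supersedes: {HAA9: HAA5}
aliases:
  NITRATE_NITRITE: NITRATE
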