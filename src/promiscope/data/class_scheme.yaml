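# Ordered keyword rules assigning protein targets to eight classes.
# Each rule's pattern is matched case-insensitively as a substring of the
# target's family name and protein name; the first matching rule wins, so
# specific patterns (e.g. "g protein-coupled receptor") precede generic
# fallbacks (e.g. "receptor"). Targets matching no rule are Unclassified;
# "Others" is only ever assigned through an explicit class_label column.
rules:
  - {pattern: "g protein-coupled", class: "G protein-coupled receptors"}
  - {pattern: "g-protein coupled", class: "G protein-coupled receptors"}
  - {pattern: "gpcr", class: "G protein-coupled receptors"}
  - {pattern: "transcription factor", class: "Transcription factors"}
  - {pattern: "nuclear receptor", class: "Transcription factors"}
  - {pattern: "ion channel", class: "Ion channels"}
  - {pattern: "channel", class: "Ion channels"}
  - {pattern: "solute carrier", class: "Transporters"}
  - {pattern: "transporter", class: "Transporters"}
  - {pattern: "kinase", class: "Enzymes"}
  - {pattern: "phosphatase", class: "Enzymes"}
  - {pattern: "protease", class: "Enzymes"}
  - {pattern: "peptidase", class: "Enzymes"}
  - {pattern: "hydrolase", class: "Enzymes"}
  - {pattern: "transferase", class: "Enzymes"}
  - {pattern: "oxidoreductase", class: "Enzymes"}
  - {pattern: "reductase", class: "Enzymes"}
  - {pattern: "oxidase", class: "Enzymes"}
  - {pattern: "synthase", class: "Enzymes"}
  - {pattern: "synthetase", class: "Enzymes"}
  - {pattern: "ligase", class: "Enzymes"}
  - {pattern: "lyase", class: "Enzymes"}
  - {pattern: "isomerase", class: "Enzymes"}
  - {pattern: "esterase", class: "Enzymes"}
  - {pattern: "deacetylase", class: "Enzymes"}
  - {pattern: "polymerase", class: "Enzymes"}
  - {pattern: "enzyme", class: "Enzymes"}
  - {pattern: "receptor", class: "Receptors"}
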