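# Example visual style for a metabolic network with functional modules.
# Module entries take precedence over class entries, which take precedence
# over the default glyph.
modules:
  central_metabolism: {shape: square, fill: "#d62728"}
  lipid_synthesis: {shape: ellipse, fill: "#1f77b4"}
  nucleotide_synthesis: {shape: rectangle, fill: "#2ca02c"}
  cell_wall_synthesis: {shape: diamond, fill: "#d62728"}
  virulence_factor_synthesis: {shape: square, fill: "#e31a1c"}
  trna_synthetases: {shape: diamond, fill: "#08306b"}
  ethanol_pyruvate_metabolism: {shape: rectangle, fill: "#08519c"}
  sulfur_metabolism: {shape: round-rectangle, fill: "#9ecae1"}
  unassigned: {shape: circle, fill: "#ffd92f"}
classes:
  metabolite: {shape: ellipse, fill: "#3182bd"}
  reaction: {shape: square, fill: "#bdbdbd"}
default: {shape: circle, fill: "#9ecae1"}
edge_color: "#b0b0b0"
edge_width: 1.0
cell_size: 18
label_mode: none
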