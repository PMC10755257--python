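# keyword -> function mapping (editable).
# Matching is case-insensitive on the full pdbx_keywords string; unknown
# keywords pass through unmapped.  Extend or edit rows freely.
OXIDOREDUCTASE	Oxidoreductase
OXIDOREDUCTASE (OXYGENASE)	Oxidoreductase
OXIDOREDUCTASE (H2O2(A))	Oxidoreductase
ELECTRON TRANSPORT	Electron transport
ELECTRON TRANSFER	Electron transport
ELECTRON TRANSPORT (HEME PROTEIN)	Electron transport
OXYGEN STORAGE/TRANSPORT	Oxygen binding
OXYGEN TRANSPORT	Oxygen binding
OXYGEN STORAGE	Oxygen binding
OXYGEN BINDING	Oxygen binding
TRANSPORT PROTEIN	Transport
METAL TRANSPORT	Transport
SIGNALING PROTEIN	Signaling
TRANSCRIPTION	Transcription
GENE REGULATION	Transcription
HYDROLASE	Hydrolase
LYASE	Lyase
ISOMERASE	Isomerase
TRANSFERASE	Transferase
LIGASE	Ligase
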