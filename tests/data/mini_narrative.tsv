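gEGR2	transcription factor controlling Schwann cell differentiation in peripheral nerves
gGPI	glycolytic enzyme central to glucose metabolic process
gMPZ	structural protein driving myelination of peripheral axons
gPMP22	membrane protein required for myelination and myelin stability
gPOLG	mitochondrial polymerase supporting axon ensheathment indirectly
gPRX	scaffold protein organizing the myelination machinery
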