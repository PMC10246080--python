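format-version: 1.4
ontology: mini-fixture

[Term]
id: MINI:0000001
name: biological process

[Term]
id: MINI:0000002
name: myelination
synonym: "myelin formation" EXACT []
is_a: MINI:0000004

[Term]
id: MINI:0000003
name: Schwann cell differentiation
is_a: MINI:0000001

[Term]
id: MINI:0000004
name: axon ensheathment
is_a: MINI:0000001

[Term]
id: MINI:0000005
name: glucose metabolic process
is_a: MINI:0000001

[Term]
id: MINI:0000006
name: myelin maintenance
synonym: "myelin sheath maintenance" EXACT []
is_obsolete: true
replaced_by: MINI:0000002
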