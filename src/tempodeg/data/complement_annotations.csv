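# Complement-system annotations for the 11 complement genes carried on the
# neuroinflammation panel (editable fixture). Class vocabulary:
# initiator/enzyme/effector/receptor/regulator; pathway vocabulary:
# classical/lectin/alternative/terminal/effector.
gene_id,complement_class,complement_pathway
C1qa,initiator,classical
C1qb,initiator,classical
C1qc,initiator,classical
C3,effector,effector
C4a,effector,classical
C6,effector,terminal
C3ar1,receptor,effector
C5ar1,receptor,effector
Itgam,receptor,effector
Itgax,receptor,effector
Serping1,regulator,classical
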