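# Declarative category review edits, applied in order after automatic
# category building.  The default review makes no edits.
[]
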