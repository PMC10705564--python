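box:
  center:
  - 0.0
  - 0.0
  - 0.0
  half_widths:
  - 3.284
  - 3.21
  - 3.2569999999999997
case_id: clash_fixture
difficulty: challenging
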