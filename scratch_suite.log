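........................................................................ [ 34%]
........................................................................ [ 69%]
..............................................................           [100%]
=============================== warnings summary ===============================
tests/test_model.py::TestAnchoring::test_totals_identical_across_configs
tests/test_protocols.py::TestFourTrainLTP::test_total_ca_pulses
  /opt/conda/envs/bio/lib/python3.11/site-packages/_pytest/fixtures.py:1313: PytestRemovedIn10Warning: Class-scoped fixture defined as instance method is deprecated.
  Instance attributes set in this fixture will NOT be visible to test methods,
  as each test gets a new instance while the fixture runs only once per class.
  Use @classmethod decorator and set attributes on cls instead.
  See https://docs.pytest.org/en/stable/deprecations.html#class-scoped-fixture-as-instance-method
    fixturefunc = resolve_fixture_function(fixturedef, request)

-- Docs: https://docs.pytest.org/en/stable/how-to/capture-warnings.html
206 passed, 2 warnings in 909.04s (0:15:09)
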