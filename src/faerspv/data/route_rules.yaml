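# Keyword rulebook for classifying a semaglutide case's formulation.
# Fields are tried in precedence order: route, dose_form, drugname, dose_freq.
# Matching is case-insensitive substring against the case's target-drug rows.
# Keyword sets live here rather than in code because FAERS free text drifts.
route:
  oral:
    - oral
    - po
  subcutaneous:
    - subcutaneous
    - subcut
    - sub-q
    - sc
dose_form:
  oral:
    - tablet
    - tab
  subcutaneous:
    - solution for injection
    - solution
    - injection
    - pen
    - prefilled syringe
drugname:
  oral:
    - rybelsus
  subcutaneous:
    - ozempic
    - wegovy
dose_freq:
  oral:
    - qd
    - daily
  subcutaneous:
    - qw
    - weekly
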