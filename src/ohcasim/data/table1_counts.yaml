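# Stratified cohort characteristics used by the table-faithful generator.
# Four strata: exposure (alert_issued) x outcome (bcpr). Counts are cases per
# covariate level within the stratum; age is summarised by printed quartiles.
total: 13274
age_by_alert:
  alert0: {q1: 58.0, median: 70.0, q3: 82.0}
  alert1: {q1: 60.0, median: 72.0, q3: 83.0}
strata:
  - alert_issued: 0
    bcpr: 0
    total: 3615
    age: {q1: 58.5, median: 70.0, q3: 82.0}
    gender: {female: 1291, male: 2324}
    witness_type: {not_witnessed: 1847, family: 1091, healthcare: 40, lay: 637}
    arrest_location: {home: 2819, public: 796}
    call_time: {t00_05: 587, t06_18: 2252, t19_23: 776}
    first_rhythm: {non_shockable: 3199, shockable: 410, unknown: 6}
  - alert_issued: 1
    bcpr: 0
    total: 993
    age: {q1: 63.0, median: 74.0, q3: 84.0}
    gender: {female: 376, male: 617}
    witness_type: {not_witnessed: 629, family: 280, healthcare: 4, lay: 80}
    arrest_location: {home: 911, public: 82}
    call_time: {t00_05: 127, t06_18: 667, t19_23: 199}
    first_rhythm: {non_shockable: 902, shockable: 89, unknown: 2}
  - alert_issued: 0
    bcpr: 1
    total: 2783
    age: {q1: 57.0, median: 69.0, q3: 82.0}
    gender: {female: 875, male: 1908}
    witness_type: {not_witnessed: 1193, family: 592, healthcare: 471, lay: 527}
    arrest_location: {home: 1300, public: 1483}
    call_time: {t00_05: 390, t06_18: 1875, t19_23: 518}
    first_rhythm: {non_shockable: 2126, shockable: 599, unknown: 58}
  - alert_issued: 1
    bcpr: 1
    total: 5883
    age: {q1: 60.0, median: 72.0, q3: 83.0}
    gender: {female: 2315, male: 3568}
    witness_type: {not_witnessed: 3014, family: 2007, healthcare: 128, lay: 734}
    arrest_location: {home: 5023, public: 860}
    call_time: {t00_05: 809, t06_18: 3899, t19_23: 1175}
    first_rhythm: {non_shockable: 4839, shockable: 993, unknown: 51}
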