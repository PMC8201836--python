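# Default planning objectives for the 30 Gy / 5-fraction SFRT boost.
#
# CTV aims:   D90% = prescription; V45Gy >= 50-55 %; V60Gy >= 30 %.
# OAR aims:   per-structure boost D2cm3 aim with an upper hard limit (Gy);
#             the aims correspond to cumulative EQD2 limits (alpha/beta = 3)
#             of 80 / 65 / 70 / 65 Gy for bladder / rectum / sigmoid / bowel
#             once summed with a uniform prior EBRT course of 45 Gy in 25 fx.
prescription_gy: 30.0
n_fractions: 5
ctv:
  d90_gy: 30.0
  v45_aim_pct: 50.0
  v60_aim_pct: 30.0
oars:
  bladder: {aim_gy: 23.75, hard_gy: 27.5, cumulative_eqd2_gy: 80.0}
  rectum: {aim_gy: 17.0, hard_gy: 19.45, cumulative_eqd2_gy: 65.0}
  sigmoid: {aim_gy: 19.5, hard_gy: 21.65, cumulative_eqd2_gy: 70.0}
  bowel: {aim_gy: 17.0, hard_gy: 19.45, cumulative_eqd2_gy: 65.0}
prior_course:
  total_gy: 45.0
  n_fractions: 25
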