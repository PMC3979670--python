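"""Build the synthetic stand-in cohort matrices (day 1, 2, 4, 6).

The published record gives, for each cohort: the total transition count,
the number of significant transitions, per-day high-intensity involvement,
and the cross-age persistence structure (20 common to all ages, 8 from
day 2, 5 from day 3, 4 on days 4+6, 3 on day 6 only, Av-W/Wr-W on days
1-3 only, R-U on days 1-4 only).  This script engineers count matrices
realizing exactly that structure around the real day-3 matrix.
"""
import warnings
from importlib import resources

import ethoseq as es
from ethoseq.synthetic import engineer_significance_matrix

warnings.simplefilter("ignore")

eth = es.default_ethogram()
with resources.as_file(es.packaged_matrix_path(3)) as p:
    tc3 = es.read_transition_matrix(p, eth, age_days=3)
res3 = es.QuasiIndependence(tc3).fit()
S3 = res3.significant_transitions()
assert len(S3) == 55

HI = {"L", "H", "Wr", "I"}

C20 = {
    ("U", "Wr"), ("Ap", "L"), ("Lo", "L"), ("Ap", "I"),
    ("U", "W"), ("W", "U"), ("W", "Ap"), ("Ap", "Av"), ("Ap", "R"),
    ("Av", "U"), ("Av", "R"), ("Av", "Lo"), ("G", "T"), ("G", "Sta"),
    ("Sta", "G"), ("Sta", "Av"), ("Sta", "R"), ("R", "W"), ("Sti", "Sta"), ("T", "Av"),
}
B8 = {("H", "Wr"), ("L", "Wr"), ("I", "Wr"), ("Wr", "I"), ("T", "L"),
      ("G", "B"), ("B", "Sta"), ("Sta", "J")}
C3_5 = {("Wr", "U"), ("Wr", "H"), ("J", "T"), ("J", "Sta"), ("Sta", "Sti")}
F123 = {("Av", "W"), ("Wr", "W")}
F1234 = {("R", "U")}
D4 = {("Ap", "Sti"), ("J", "U"), ("R", "J"), ("Sti", "G")}
E6 = {("R", "Wr"), ("Wr", "L"), ("B", "G")}

for name, s in [("C20", C20), ("B8", B8), ("C3_5", C3_5), ("F123", F123), ("F1234", F1234)]:
    missing = s - S3
    assert not missing, (name, missing)

extra1 = {("J", "W"), ("L", "W"), ("Lo", "Sti"), ("L", "Lo"), ("I", "U"),
          ("H", "U"), ("Sti", "Av"), ("U", "Sta"), ("Av", "T"), ("T", "Ap"),
          ("Sta", "T"), ("I", "W"), ("G", "Sti"), ("Lo", "Av"), ("Lo", "U")}
extra2 = {("Av", "B"), ("Av", "J"), ("Av", "Sti"), ("H", "I"), ("H", "R"),
          ("H", "W"), ("I", "H"), ("J", "B"), ("J", "I"), ("R", "B"),
          ("Sti", "L"), ("T", "Lo"), ("U", "H"), ("U", "I"),
          ("I", "U"), ("H", "U"), ("Sti", "Lo"), ("Av", "T"), ("T", "Ap"),
          ("J", "Av"), ("R", "I"), ("Wr", "R"),
          ("Wr", "Sta"), ("I", "W"), ("L", "U"), ("H", "Sta"), ("U", "G")}
extra4 = {("J", "L"), ("L", "Lo"), ("Sti", "Lo"), ("I", "U"), ("U", "Sta"),
          ("Sti", "Av"), ("Sta", "T"), ("Wr", "Sta"), ("I", "W"), ("G", "Sti"),
          ("T", "W"), ("Av", "Ap"), ("U", "G"), ("Lo", "Av"), ("J", "R"), ("Ap", "Lo")}
extra6 = {("H", "U"), ("Wr", "R"), ("U", "Sta"), ("Av", "T"), ("T", "Ap"),
          ("Sta", "T"), ("L", "U"), ("H", "Sta"), ("I", "W"), ("Sti", "Av"),
          ("Lo", "Sti"), ("G", "Sti"), ("Lo", "U")}

S1 = C20 | F123 | F1234 | extra1
S2 = C20 | B8 | F123 | F1234 | extra2
S4 = C20 | B8 | C3_5 | D4 | F1234 | extra4
S6 = C20 | B8 | C3_5 | D4 | E6 | extra6
sets = {1: S1, 2: S2, 3: S3, 4: S4, 6: S6}
for age, size in [(1, 38), (2, 58), (3, 55), (4, 54), (6, 53)]:
    assert len(sets[age]) == size, (age, len(sets[age]))
common = set.intersection(*sets.values())
assert common == C20, ("common", len(common), common ^ C20)
for age, hi_n in [(1, 10), (2, 26), (3, 18), (4, 16), (6, 18)]:
    hi = {(a, b) for a, b in sets[age] if a in HI or b in HI}
    assert len(hi) == hi_n, (age, len(hi), sorted(hi))

totals = {1: 5075, 2: 5990, 4: 5203, 6: 7206}
for age, total in totals.items():
    tc = engineer_significance_matrix(tc3, sets[age], total)
    res = es.QuasiIndependence(tc).fit()
    assert res.significant_transitions() == sets[age], (age, res.significant_transitions() ^ sets[age])
    assert tc.total == total, (age, tc.total)
    path = f"src/ethoseq/data/synthetic/transitions_day{age}_synthetic.tsv"
    es.write_transition_matrix(tc, path)
    print(f"day {age}: total {tc.total}, sig {len(sets[age])} -> {path}")

# end-to-end persistence check on the written fixtures
fits = {}
for age in (1, 2, 3, 4, 6):
    with resources.as_file(es.packaged_matrix_path(age)) as p:
        tc = es.read_transition_matrix(p, eth, age_days=age)
    fits[age] = es.QuasiIndependence(tc).fit()
classes = es.cohort_persistence_classes(fits)
print("common_all:", len(classes.common_all))
print("appears:", {d: len(s) for d, s in classes.appears_from_day.items()})
print("disappears:", {d: len(s) for d, s in classes.disappears_after_day.items()})
print("other:", len(classes.other))
assert len(classes.common_all) == 20
assert {d: len(s) for d, s in classes.appears_from_day.items()} == {2: 8, 3: 5, 4: 4, 6: 3}
assert classes.disappears_after_day[3] == F123
assert classes.disappears_after_day[4] == F1234
print("all checks passed")
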