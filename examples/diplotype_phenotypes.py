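"""Translate CYP2D6 diplotypes into activity scores and metaboliser classes.

Walks through the cohort's notable genotypes: the *4/*5 poor metaboliser
(both alleles score 0), the *1x2/*1 ultra-rapid metaboliser (the
duplication contributes 2 x 1), and a *71 carrier whose phenotype is
uncertain because *71's function is unresolved.  Then reruns the *71
carrier under a what-if table in which *71 is treated as nonfunctional —
the scenario that would reclassify much of the cohort.
"""

from pgxstar import FunctionClass, builtin_table, call_phenotype, reassign_function
from pgxstar.diplotype import Diplotype

table = builtin_table("CYP2D6")
for a, b in [("*4", "*5"), ("*1x2", "*1"), ("*71", "*1"), ("*71", "*4")]:
    call = call_phenotype(Diplotype("demo", a, b), table)
    score = "undefined" if call.activity_score is None else call.activity_score
    print(f"{a}/{b:6s} activity={score!s:10s} phenotype={call.phenotype.value}")

print("\nscenario: *71 reassigned to no-function (activity 0)")
scenario = reassign_function(table, "*71", FunctionClass.NO_FUNCTION, 0.0)
for a, b in [("*71", "*1"), ("*71", "*4")]:
    call = call_phenotype(Diplotype("demo", a, b), scenario)
    print(f"{a}/{b:6s} activity={call.activity_score!s:10s} "
          f"phenotype={call.phenotype.value}")
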