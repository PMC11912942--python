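"""Bundled reference condition summary for worked examples.

Condition-level mean (SD) stride-normalized CCI values reported by a
published comparison of conventional (Dry) and aquatic (Wet) treadmill
walking at three speeds in typically developing children (TD) and children
with cerebral palsy (CP), for the RF/ST and TA/MG muscle pairings under all
three CCI formulas. These serve as worked-example inputs to the contrast
operations: feeding the cell means to :func:`ccigait.stats.environment_contrast`
and :func:`ccigait.stats.speed_contrast` reproduces the narrative percent
changes of that comparison (e.g. a 41.3% Wet reduction for CP children with
the Unnithan formula on RF/ST).

Units: Unnithan in normalized activation x %stride, Rudolph in normalized
activation, Falconer & Winter in percent.
"""

from __future__ import annotations

import io

import pandas as pd

_REFERENCE_CSV = """\
pairing,method,population,environment,speed,mean,sd
RF/ST,unnithan,CP,Dry,Slow,16.66,6.26
RF/ST,unnithan,CP,Wet,Slow,9.81,4.66
RF/ST,unnithan,CP,Dry,Normal,19.39,6.62
RF/ST,unnithan,CP,Wet,Normal,10.43,4.98
RF/ST,unnithan,CP,Dry,Fast,22.87,7.52
RF/ST,unnithan,CP,Wet,Fast,14.37,8.07
RF/ST,unnithan,TD,Dry,Slow,11.84,4.60
RF/ST,unnithan,TD,Wet,Slow,9.74,6.61
RF/ST,unnithan,TD,Dry,Normal,14.89,4.81
RF/ST,unnithan,TD,Wet,Normal,10.81,7.31
RF/ST,unnithan,TD,Dry,Fast,19.79,5.42
RF/ST,unnithan,TD,Wet,Fast,13.43,8.90
RF/ST,rudolph,CP,Dry,Slow,0.27,0.11
RF/ST,rudolph,CP,Wet,Slow,0.15,0.08
RF/ST,rudolph,CP,Dry,Normal,0.31,0.11
RF/ST,rudolph,CP,Wet,Normal,0.16,0.08
RF/ST,rudolph,CP,Dry,Fast,0.37,0.14
RF/ST,rudolph,CP,Wet,Fast,0.22,0.13
RF/ST,rudolph,TD,Dry,Slow,0.19,0.08
RF/ST,rudolph,TD,Wet,Slow,0.15,0.10
RF/ST,rudolph,TD,Dry,Normal,0.24,0.08
RF/ST,rudolph,TD,Wet,Normal,0.16,0.11
RF/ST,rudolph,TD,Dry,Fast,0.32,0.10
RF/ST,rudolph,TD,Wet,Fast,0.20,0.14
RF/ST,fw,CP,Dry,Slow,99.98,14.55
RF/ST,fw,CP,Wet,Slow,104.08,20.32
RF/ST,fw,CP,Dry,Normal,96.31,18.28
RF/ST,fw,CP,Wet,Normal,102.63,19.38
RF/ST,fw,CP,Dry,Fast,97.21,16.97
RF/ST,fw,CP,Wet,Fast,98.77,19.40
RF/ST,fw,TD,Dry,Slow,94.42,20.64
RF/ST,fw,TD,Wet,Slow,92.06,28.98
RF/ST,fw,TD,Dry,Normal,95.89,20.83
RF/ST,fw,TD,Wet,Normal,91.56,30.16
RF/ST,fw,TD,Dry,Fast,95.81,13.00
RF/ST,fw,TD,Wet,Fast,90.83,28.81
TA/MG,unnithan,CP,Dry,Slow,15.70,5.86
TA/MG,unnithan,CP,Wet,Slow,11.32,5.56
TA/MG,unnithan,CP,Dry,Normal,17.83,6.31
TA/MG,unnithan,CP,Wet,Normal,12.82,6.29
TA/MG,unnithan,CP,Dry,Fast,20.78,6.73
TA/MG,unnithan,CP,Wet,Fast,16.44,8.04
TA/MG,unnithan,TD,Dry,Slow,6.22,1.78
TA/MG,unnithan,TD,Wet,Slow,4.97,1.76
TA/MG,unnithan,TD,Dry,Normal,7.54,2.94
TA/MG,unnithan,TD,Wet,Normal,5.75,1.88
TA/MG,unnithan,TD,Dry,Fast,9.90,4.04
TA/MG,unnithan,TD,Wet,Fast,7.76,3.72
TA/MG,rudolph,CP,Dry,Slow,0.25,0.11
TA/MG,rudolph,CP,Wet,Slow,0.17,0.09
TA/MG,rudolph,CP,Dry,Normal,0.28,0.12
TA/MG,rudolph,CP,Wet,Normal,0.20,0.10
TA/MG,rudolph,CP,Dry,Fast,0.33,0.13
TA/MG,rudolph,CP,Wet,Fast,0.25,0.13
TA/MG,rudolph,TD,Dry,Slow,0.08,0.03
TA/MG,rudolph,TD,Wet,Slow,0.07,0.03
TA/MG,rudolph,TD,Dry,Normal,0.10,0.05
TA/MG,rudolph,TD,Wet,Normal,0.08,0.03
TA/MG,rudolph,TD,Dry,Fast,0.14,0.06
TA/MG,rudolph,TD,Wet,Fast,0.10,0.05
TA/MG,fw,CP,Dry,Slow,96.58,14.68
TA/MG,fw,CP,Wet,Slow,92.21,32.13
TA/MG,fw,CP,Dry,Normal,98.29,14.06
TA/MG,fw,CP,Wet,Normal,92.20,30.08
TA/MG,fw,CP,Dry,Fast,98.10,12.33
TA/MG,fw,CP,Wet,Fast,91.53,29.42
TA/MG,fw,TD,Dry,Slow,79.59,9.83
TA/MG,fw,TD,Wet,Slow,68.77,13.02
TA/MG,fw,TD,Dry,Normal,82.58,9.36
TA/MG,fw,TD,Wet,Normal,67.46,10.97
TA/MG,fw,TD,Dry,Fast,82.40,10.62
TA/MG,fw,TD,Wet,Fast,64.93,13.76
"""


def reference_summary() -> pd.DataFrame:
    """Reference condition summary as a tidy DataFrame.

    Columns: pairing, method, population, environment, speed, mean, sd —
    the same layout :func:`ccigait.stats.summarize_conditions` produces
    (without n_limbs), so the contrast operations accept it directly.
    """
    return pd.read_csv(io.StringIO(_REFERENCE_CSV))
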