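"""Brute-force oracles shared across test modules."""

import math

import numpy as np


def naive_glcm(patch, levels, offset, symmetric):
    """Brute-force double-loop co-occurrence counting."""
    dr, dc = offset
    counts = np.zeros((levels, levels))
    h, w = patch.shape
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < h and 0 <= j2 < w:
                counts[patch[i, j], patch[i2, j2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def naive_stats(P):
    """Brute-force double-loop evaluation of the eight texture statistics."""
    N = P.shape[0]
    mean = sum(i * P[i, j] for i in range(N) for j in range(N))
    mu_j = sum(j * P[i, j] for i in range(N) for j in range(N))
    var = sum((i - mean) ** 2 * P[i, j] for i in range(N) for j in range(N))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(N) for j in range(N))
    hom = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(N) for j in range(N))
    con = sum((i - j) ** 2 * P[i, j] for i in range(N) for j in range(N))
    dis = sum(abs(i - j) * P[i, j] for i in range(N) for j in range(N))
    ent = -sum(P[i, j] * math.log(P[i, j])
               for i in range(N) for j in range(N) if P[i, j] > 0)
    sm = sum(P[i, j] ** 2 for i in range(N) for j in range(N))
    if var <= 0 or var_j <= 0:
        corr = 1.0
    else:
        corr = sum((i - mean) * (j - mu_j) * P[i, j]
                   for i in range(N) for j in range(N)) / math.sqrt(var * var_j)
    return dict(mean=mean, var=var, hom=hom, con=con, dis=dis, ent=ent,
                sm=sm, corr=corr)


from needlegrade.vegindex import SpectralSample  # noqa: E402

# Independently recomputed values of every registered formula at three
# fixed reflectance points (R,G,B = r,g,b; RE; NIR):
#   P1 = (0.12, 0.48, 0.10, RE=0.44, NIR=0.71)  healthy-like
#   P2 = (0.55, 0.35, 0.18, RE=0.40, NIR=0.50)  moderate-like
#   P3 = (0.41, 0.40, 0.38, RE=0.37, NIR=0.33)  severe-like
POINTS = [
    SpectralSample(R=0.12, G=0.48, B=0.10, b=0.10, g=0.48, r=0.12,
                   RE=0.44, NIR=0.71),
    SpectralSample(R=0.55, G=0.35, B=0.18, b=0.18, g=0.35, r=0.55,
                   RE=0.40, NIR=0.50),
    SpectralSample(R=0.41, G=0.40, B=0.38, b=0.38, g=0.40, r=0.41,
                   RE=0.37, NIR=0.33),
]

GOLDEN = {
    'R': (0.12, 0.55, 0.41),
    'G': (0.48, 0.35, 0.4),
    'B': (0.1, 0.18, 0.38),
    'ExG': (0.74, -0.030000000000000082, 0.010000000000000064),
    'ExR': (-0.312, 0.42000000000000004, 0.17399999999999993),
    'GBRI': (4.8, 1.9444444444444444, 1.0526315789473684),
    'GCC': (0.6857142857142857, 0.324074074074074, 0.33613445378151263),
    'RBRI': (1.2, 3.055555555555556, 1.0789473684210527),
    'RGRI': (0.25, 1.5714285714285716, 1.025),
    'VDVI': (0.37142857142857144, -0.35185185185185186, -0.3277310924369748),
    'GLA': (0.6271186440677965, -0.02097902097902104, 0.00628930817610067),
    'CIVE': (18.45605, 18.791058, 18.762388),
    'GB': (0.38, 0.16999999999999998, 0.020000000000000018),
    'VARI': (0.72, -0.2777777777777779, -0.02325581395348826),
    'GRVI': (0.6, -0.2222222222222223, -0.012345679012345621),
    'NGRVI': (0.8823529411764706, -0.42352941176470593, -0.024687595245351846),
    'PPR': (0.6551724137931035, 0.320754716981132, 0.025641025641025664),
    'WI': (-1.0555555555555556, 0.8499999999999996, 2.000000000000011),
    'ExGR': (1.052, -0.4500000000000001, -0.16399999999999987),
    'RGBVI': (0.9009900990099009, 0.10609480812641076, 0.013299556681444068),
    '2NLI': (0.024489381160451185, -0.16666666666666663, -0.5720180782078994),
    'GDVI': (0.22999999999999998, 0.15000000000000002, -0.07),
    'GMNLI': (0.29842971376047334, 0.34400991521701374, 0.1774785751560741),
    'NDVIreg': (0.23478260869565215, 0.11111111111111108, -0.05714285714285712),
    'SI1reg': (0.4595650117230423, 0.3741657386773941, 0.3847076812334269),
    'SI1reg*': (0.22978250586152116, 0.469041575982343, 0.3894868418830089),
    'TCARI': (1.048, -0.4718181818181819, -0.10375609756097554),
    'MTVI2': (1.0488762842464214, -0.23399051353252845, -0.08768095818558233),
    'Int2reg*': (0.52, 0.65, 0.5900000000000001),
    'NDSIreg': (-0.23478260869565215, -0.11111111111111108, 0.05714285714285712),
    'RECI': (0.6136363636363635, 0.25, -0.108108108108108),
    'SCCI': (250.09352180004265, 200.15137758908207, 200.7846673449905),
    'SI2reg': (0.9633794683301071, 0.7297259759663212, 0.6370243323453195),
}


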