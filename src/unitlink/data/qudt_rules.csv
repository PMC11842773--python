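# Default qudt-phase substitutions: pseudounit -> marked QUDT candidate.
# Replacements are dash-delimited, QUDT-cased tokens; because pseudounits
# contain no dashes, converted segments are visibly distinct from text not
# yet converted. Ordered longest-fragment-first within each concept family;
# tokens embedding other unit words (centimetersquared, percent, permille)
# fire before their fragments (metersquared, cent..., per).
order,pattern,replacement
# --- temperature (whole-form variants and misspellings first) ---
10,"degreescelcius","-DEG_C-"
12,"degreecelcius","-DEG_C-"
14,"degreescelsius","-DEG_C-"
16,"degreecelsius","-DEG_C-"
18,"celcius","-DEG_C-"
20,"celsius","-DEG_C-"
22,"degc","-DEG_C-"
24,"degreesfahrenheit","-DEG_F-"
26,"degreefahrenheit","-DEG_F-"
28,"fahrenheit","-DEG_F-"
30,"degf","-DEG_F-"
32,"kelvin","-K-"
34,"degrees","-DEG-"
36,"degree","-DEG-"
38,"deg","-DEG-"
# --- exponent compounds (before their base-unit fragments) ---
100,"centimetersquared","-CentiM2-"
102,"millimetersquared","-MilliM2-"
104,"kilometersquared","-KiloM2-"
106,"metersquared","-M2-"
108,"centimetercubed","-CentiM3-"
110,"metercubed","-M3-"
112,"hectare","-HA-"
# --- length ---
200,"micrometer","-MicroM-"
202,"micron","-MicroM-"
204,"nanometer","-NanoM-"
206,"centimeter","-CentiM-"
207,"cenimeter","-CentiM-"
208,"millimeter","-MilliM-"
210,"kilometer","-KiloM-"
212,"meter","-M-"
# --- time ---
220,"second","-SEC-"
222,"minute","-MIN-"
224,"hour","-HR-"
226,"day","-DAY-"
228,"year","-YR-"
# --- mass ---
240,"microgram","-MicroGM-"
242,"milligram","-MilliGM-"
244,"kilogram","-KiloGM-"
246,"gram","-GM-"
# --- volume ---
260,"milliliter","-MilliL-"
262,"microliter","-MicroL-"
264,"liter","-L-"
# --- amount of substance ---
270,"micromole","-MicroMOL-"
272,"millimole","-MilliMOL-"
274,"mole","-MOL-"
276,"mol","-MOL-"
# --- pressure ---
280,"kilopascal","-KiloPA-"
282,"hectopascal","-HectoPA-"
284,"pascal","-PA-"
286,"kpa","-KiloPA-"
288,"hpa","-HectoPA-"
# --- energy, power, frequency ---
300,"joule","-J-"
302,"watt","-W-"
304,"hertz","-HZ-"
# --- dimensionless (after centi- compounds so percent cannot steal) ---
400,"percentage","-PERCENT-"
402,"percent","-PERCENT-"
404,"permille","-PERMILLE-"
406,"permil","-PERMILLE-"
408,"dimensionless","-UNITLESS-"
410,"unitless","-UNITLESS-"
412,"number","-NUM-"
414,"count","-NUM-"
# --- the divider, last of all ---
900,"per","-PER-"
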