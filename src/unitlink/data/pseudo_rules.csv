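# Default pseudo-phase substitutions: raw unit text -> pseudounit.
# Applied in `order` after Unicode NFKD + lowercasing; the working string is
# space-padded and whitespace-collapsed, so patterns quoted with surrounding
# spaces anchor on whole tokens. All whitespace and non-[a-z0-9] characters
# are deleted after the last rule.
order,pattern,replacement
# --- symbols to words / separators ---
10,"μ","micro"
12,"µ","micro"
14,"°"," deg "
16,"%"," percent "
18,"‰"," permil "
20,"/"," per "
22,"^",""
24,"**",""
26,"*"," "
28,"·"," "
30,"⋅"," "
32,"("," "
34,")"," "
36,"["," "
38,"]"," "
40,","," "
42,"."," "
44,"_"," "
46,"#"," number "
48,";"," "
# --- misspellings and variant spellings ---
100,"metre","meter"
102,"cenimeter","centimeter"
104,"litre","liter"
106,"celcius","celsius"
108,"cubitmeter","cubicmeter"
110,"farenheit","fahrenheit"
112,"gramme","gram"
114,"reciprocal","per "
115,"inverse","per "
116,"percentage","percent"
118,"parts per thousand","permil"
# --- spelled-out exponent compounds -> abbreviated tokens ---
# (prefixed lengths first: centimetersquared contains metersquared)
140,"centimeters squared"," cm2 "
141,"centimeter squared"," cm2 "
142,"centimetersquared"," cm2 "
143,"square centimeters"," cm2 "
144,"square centimeter"," cm2 "
145,"squarecentimeter"," cm2 "
146,"millimeters squared"," mm2 "
147,"millimeter squared"," mm2 "
148,"millimetersquared"," mm2 "
149,"square millimeters"," mm2 "
150,"square millimeter"," mm2 "
151,"squaremillimeter"," mm2 "
152,"kilometers squared"," km2 "
153,"kilometer squared"," km2 "
154,"kilometersquared"," km2 "
155,"square kilometers"," km2 "
156,"square kilometer"," km2 "
157,"squarekilometer"," km2 "
158,"meters squared"," m2 "
159,"meter squared"," m2 "
160,"metersquared"," m2 "
161,"square meters"," m2 "
162,"square meter"," m2 "
163,"squaremeter"," m2 "
164,"cubic centimeters"," cm3 "
165,"cubic centimeter"," cm3 "
166,"cubiccentimeter"," cm3 "
167,"centimeters cubed"," cm3 "
168,"centimeter cubed"," cm3 "
169,"centimetercubed"," cm3 "
170,"cubic meters"," m3 "
171,"cubic meter"," m3 "
172,"cubicmeter"," m3 "
173,"meters cubed"," m3 "
174,"meter cubed"," m3 "
175,"metercubed"," m3 "
# --- plural to singular (safe only after compounds are tokenized) ---
240,"grams","gram"
242,"meters","meter"
244,"liters","liter"
246,"moles","mole"
248,"seconds","second"
250,"minutes","minute"
252,"hours","hour"
254,"days","day"
256,"years","year"
258,"degrees","degree"
260,"hectares","hectare"
262,"numbers","number"
264,"pascals","pascal"
266,"watts","watt"
268,"joules","joule"
270,"kelvins","kelvin"
272,"counts","count"
# --- abbreviation tokens with exponents ---
310," gm-2 "," gram permetersquared "
312," ms-1 "," meter persecond "
314," m-1 "," permeter "
316," m-2 "," permetersquared "
318," m-3 "," permetercubed "
320," m2 "," metersquared "
322," m3 "," metercubed "
324," cm-2 "," percentimetersquared "
326," cm2 "," centimetersquared "
328," cm-3 "," percentimetercubed "
330," cm3 "," centimetercubed "
332," km2 "," kilometersquared "
334," km-2 "," perkilometersquared "
336," mm2 "," millimetersquared "
338," s-1 "," persecond "
340," s-2 "," persecondsquared "
342," sec-1 "," persecond "
344," d-1 "," perday "
346," day-1 "," perday "
348," h-1 "," perhour "
350," hr-1 "," perhour "
352," l-1 "," perliter "
354," g-1 "," pergram "
356," kg-1 "," perkilogram "
358," ha-1 "," perhectare "
360," yr-1 "," peryear "
362," y-1 "," peryear "
364," min-1 "," perminute "
# --- temperature tokens ---
370," deg c "," degreecelsius "
371," deg f "," degreefahrenheit "
372," degree c "," degreecelsius "
373," degree f "," degreefahrenheit "
# --- bare abbreviation tokens ---
380," g "," gram "
382," gm "," gram "
384," mg "," milligram "
386," kg "," kilogram "
388," ug "," microgram "
390," microg "," microgram "
392," m "," meter "
394," cm "," centimeter "
396," mm "," millimeter "
398," km "," kilometer "
400," um "," micrometer "
402," microm "," micrometer "
404," nm "," nanometer "
406," s "," second "
408," sec "," second "
410," secs "," second "
412," min "," minute "
414," hr "," hour "
416," h "," hour "
418," d "," day "
420," yr "," year "
422," l "," liter "
424," ml "," milliliter "
426," mol "," mole "
428," mmol "," millimole "
430," umol "," micromole "
432," micromol "," micromole "
434," millimol "," millimole "
436," k "," kelvin "
438," pa "," pascal "
440," kpa "," kilopascal "
442," hpa "," hectopascal "
444," ha "," hectare "
446," w "," watt "
448," j "," joule "
450," hz "," hertz "
452," pct "," percent "
454," nbr "," number "
456," no "," number "
458," deg "," degree "
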