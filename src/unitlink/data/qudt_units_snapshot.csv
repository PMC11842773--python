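# Subset of the QUDT units vocabulary, transcribed from the QUDT v2.1.25
# release (http://qudt.org/vocab/unit/). One row per unit; ucum and
# quantity_kinds cells are semicolon-separated. si_multiplier/si_offset
# convert to the coherent SI unit: si = multiplier * value + offset.
# version: 2.1.25
code,uri,label,dimension_vector,si_multiplier,si_offset,ucum,quantity_kinds,description
GM,http://qudt.org/vocab/unit/GM,gram,A0E0L0I0M1H0T0D0,0.001,0,g,Mass,0.001-fold of the SI base unit kilogram
KiloGM,http://qudt.org/vocab/unit/KiloGM,kilogram,A0E0L0I0M1H0T0D0,1,0,kg,Mass,SI base unit of mass
MilliGM,http://qudt.org/vocab/unit/MilliGM,milligram,A0E0L0I0M1H0T0D0,1e-06,0,mg,Mass,
MicroGM,http://qudt.org/vocab/unit/MicroGM,microgram,A0E0L0I0M1H0T0D0,1e-09,0,ug,Mass,
M,http://qudt.org/vocab/unit/M,metre,A0E0L1I0M0H0T0D0,1,0,m,Length,SI base unit of length
CentiM,http://qudt.org/vocab/unit/CentiM,centimetre,A0E0L1I0M0H0T0D0,0.01,0,cm,Length,
MilliM,http://qudt.org/vocab/unit/MilliM,millimetre,A0E0L1I0M0H0T0D0,0.001,0,mm,Length,
KiloM,http://qudt.org/vocab/unit/KiloM,kilometre,A0E0L1I0M0H0T0D0,1000,0,km,Length,
MicroM,http://qudt.org/vocab/unit/MicroM,micrometre,A0E0L1I0M0H0T0D0,1e-06,0,um,Length,
NanoM,http://qudt.org/vocab/unit/NanoM,nanometre,A0E0L1I0M0H0T0D0,1e-09,0,nm,Length,
M2,http://qudt.org/vocab/unit/M2,square metre,A0E0L2I0M0H0T0D0,1,0,m2,Area,SI derived unit of area
CentiM2,http://qudt.org/vocab/unit/CentiM2,square centimetre,A0E0L2I0M0H0T0D0,0.0001,0,cm2,Area,
KiloM2,http://qudt.org/vocab/unit/KiloM2,square kilometre,A0E0L2I0M0H0T0D0,1000000,0,km2,Area,
HA,http://qudt.org/vocab/unit/HA,hectare,A0E0L2I0M0H0T0D0,10000,0,har,Area,non-SI area unit accepted for use with SI
M3,http://qudt.org/vocab/unit/M3,cubic metre,A0E0L3I0M0H0T0D0,1,0,m3,Volume,
CentiM3,http://qudt.org/vocab/unit/CentiM3,cubic centimetre,A0E0L3I0M0H0T0D0,1e-06,0,cm3,Volume,
L,http://qudt.org/vocab/unit/L,litre,A0E0L3I0M0H0T0D0,0.001,0,L;l,Volume,
MilliL,http://qudt.org/vocab/unit/MilliL,millilitre,A0E0L3I0M0H0T0D0,1e-06,0,mL;ml,Volume,
SEC,http://qudt.org/vocab/unit/SEC,second,A0E0L0I0M0H0T1D0,1,0,s,Time,SI base unit of time
MIN,http://qudt.org/vocab/unit/MIN,minute,A0E0L0I0M0H0T1D0,60,0,min,Time,
HR,http://qudt.org/vocab/unit/HR,hour,A0E0L0I0M0H0T1D0,3600,0,h,Time,
DAY,http://qudt.org/vocab/unit/DAY,day,A0E0L0I0M0H0T1D0,86400,0,d,Time,
YR,http://qudt.org/vocab/unit/YR,year,A0E0L0I0M0H0T1D0,31536000,0,a,Time,
K,http://qudt.org/vocab/unit/K,kelvin,A0E0L0I0M0H1T0D0,1,0,K,ThermodynamicTemperature,SI base unit of thermodynamic temperature
DEG_C,http://qudt.org/vocab/unit/DEG_C,degree Celsius,A0E0L0I0M0H1T0D0,1,273.15,Cel,ThermodynamicTemperature,affine unit; 0 degC = 273.15 K
DEG_F,http://qudt.org/vocab/unit/DEG_F,degree Fahrenheit,A0E0L0I0M0H1T0D0,0.5555555555555556,255.37222222222223,[degF],ThermodynamicTemperature,affine unit
DEG,http://qudt.org/vocab/unit/DEG,degree,A0E0L0I0M0H0T0D1,0.017453292519943295,0,deg,PlaneAngle,
GM-PER-M2,http://qudt.org/vocab/unit/GM-PER-M2,gram per square metre,A0E0L-2I0M1H0T0D0,0.001,0,g/m2,MassPerArea,
MilliGM-PER-M2,http://qudt.org/vocab/unit/MilliGM-PER-M2,milligram per square metre,A0E0L-2I0M1H0T0D0,1e-06,0,mg/m2,MassPerArea,
KiloGM-PER-M2,http://qudt.org/vocab/unit/KiloGM-PER-M2,kilogram per square metre,A0E0L-2I0M1H0T0D0,1,0,kg/m2,MassPerArea,
KiloGM-PER-HA,http://qudt.org/vocab/unit/KiloGM-PER-HA,kilogram per hectare,A0E0L-2I0M1H0T0D0,0.0001,0,kg/har,MassPerArea,
GM-PER-CentiM2,http://qudt.org/vocab/unit/GM-PER-CentiM2,gram per square centimetre,A0E0L-2I0M1H0T0D0,10,0,g/cm2,MassPerArea,
MicroG-PER-CentiM2,http://qudt.org/vocab/unit/MicroG-PER-CentiM2,microgram per square centimetre,A0E0L-2I0M1H0T0D0,1e-05,0,ug/cm2,MassPerArea,legacy code; MicroGM-PER-CentiM2 would be the pattern-consistent form
GM-PER-M2-DAY,http://qudt.org/vocab/unit/GM-PER-M2-DAY,gram per square metre day,A0E0L-2I0M1H0T-1D0,1.1574074074074074e-08,0,g/(m2.d),MassPerAreaTime,
M-PER-SEC,http://qudt.org/vocab/unit/M-PER-SEC,metre per second,A0E0L1I0M0H0T-1D0,1,0,m/s,LinearVelocity,
CentiM-PER-SEC,http://qudt.org/vocab/unit/CentiM-PER-SEC,centimetre per second,A0E0L1I0M0H0T-1D0,0.01,0,cm/s,LinearVelocity,
KiloM-PER-HR,http://qudt.org/vocab/unit/KiloM-PER-HR,kilometre per hour,A0E0L1I0M0H0T-1D0,0.2777777777777778,0,km/h,LinearVelocity,
GM-PER-L,http://qudt.org/vocab/unit/GM-PER-L,gram per litre,A0E0L-3I0M1H0T0D0,1,0,g/L,MassConcentration,
MilliGM-PER-L,http://qudt.org/vocab/unit/MilliGM-PER-L,milligram per litre,A0E0L-3I0M1H0T0D0,0.001,0,mg/L,MassConcentration,
MicroGM-PER-L,http://qudt.org/vocab/unit/MicroGM-PER-L,microgram per litre,A0E0L-3I0M1H0T0D0,1e-06,0,ug/L,MassConcentration,
MOL,http://qudt.org/vocab/unit/MOL,mole,A1E0L0I0M0H0T0D0,1,0,mol,AmountOfSubstance,SI base unit of amount of substance
MilliMOL,http://qudt.org/vocab/unit/MilliMOL,millimole,A1E0L0I0M0H0T0D0,0.001,0,mmol,AmountOfSubstance,
MicroMOL,http://qudt.org/vocab/unit/MicroMOL,micromole,A1E0L0I0M0H0T0D0,1e-06,0,umol,AmountOfSubstance,
MOL-PER-L,http://qudt.org/vocab/unit/MOL-PER-L,mole per litre,A1E0L-3I0M0H0T0D0,1000,0,mol/L,AmountOfSubstanceConcentration,
MilliMOL-PER-L,http://qudt.org/vocab/unit/MilliMOL-PER-L,millimole per litre,A1E0L-3I0M0H0T0D0,1,0,mmol/L,AmountOfSubstanceConcentration,
MicroMOL-PER-L,http://qudt.org/vocab/unit/MicroMOL-PER-L,micromole per litre,A1E0L-3I0M0H0T0D0,0.001,0,umol/L,AmountOfSubstanceConcentration,
MicroMOL-PER-M2-SEC,http://qudt.org/vocab/unit/MicroMOL-PER-M2-SEC,micromole per square metre second,A1E0L-2I0M0H0T-1D0,1e-06,0,umol/(m2.s),PhotonFluxDensity,
PA,http://qudt.org/vocab/unit/PA,pascal,A0E0L-1I0M1H0T-2D0,1,0,Pa,Pressure,SI derived unit of pressure
KiloPA,http://qudt.org/vocab/unit/KiloPA,kilopascal,A0E0L-1I0M1H0T-2D0,1000,0,kPa,Pressure,
HectoPA,http://qudt.org/vocab/unit/HectoPA,hectopascal,A0E0L-1I0M1H0T-2D0,100,0,hPa,Pressure,
PERCENT,http://qudt.org/vocab/unit/PERCENT,percent,A0E0L0I0M0H0T0D1,0.01,0,%,DimensionlessRatio,
PERMILLE,http://qudt.org/vocab/unit/PERMILLE,per mille,A0E0L0I0M0H0T0D1,0.001,0,[ppth],DimensionlessRatio,parts per thousand
NUM,http://qudt.org/vocab/unit/NUM,number,A0E0L0I0M0H0T0D1,1,0,{#},Dimensionless,
UNITLESS,http://qudt.org/vocab/unit/UNITLESS,unitless,A0E0L0I0M0H0T0D1,1,0,,Dimensionless,
J,http://qudt.org/vocab/unit/J,joule,A0E0L2I0M1H0T-2D0,1,0,J,Energy,SI derived unit of energy
W,http://qudt.org/vocab/unit/W,watt,A0E0L2I0M1H0T-3D0,1,0,W,Power,SI derived unit of power
W-PER-M2,http://qudt.org/vocab/unit/W-PER-M2,watt per square metre,A0E0L0I0M1H0T-3D0,1,0,W/m2,HeatFluxDensity,
HZ,http://qudt.org/vocab/unit/HZ,hertz,A0E0L0I0M0H0T-1D0,1,0,Hz,Frequency,SI derived unit of frequency
PER-SEC,http://qudt.org/vocab/unit/PER-SEC,reciprocal second,A0E0L0I0M0H0T-1D0,1,0,/s,InverseTime,
PER-M2,http://qudt.org/vocab/unit/PER-M2,reciprocal square metre,A0E0L-2I0M0H0T0D0,1,0,/m2,InverseArea,
NUM-PER-M2,http://qudt.org/vocab/unit/NUM-PER-M2,number per square metre,A0E0L-2I0M0H0T0D1,1,0,,NumberDensity,
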