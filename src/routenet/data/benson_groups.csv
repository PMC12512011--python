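signature,value_kcal_per_mol,comment
C-(C)(H)3,-10.20,primary sp3 carbon
C-(C)2(H)2,-4.93,secondary sp3 carbon
C-(C)3(H),-1.90,tertiary sp3 carbon
C-(C)4,0.50,quaternary sp3 carbon
C-(Cd)(H)3,-10.20,methyl on vinyl carbon
C-(CB)(H)3,-10.20,methyl on aromatic ring
C-(CO)(H)3,-10.20,methyl on carbonyl
C-(O)(H)3,-10.20,methyl on oxygen
C-(N)(H)3,-10.20,methyl on nitrogen
C-(S)(H)3,-10.20,methyl on sulfur
C-(Cl)(H)3,-19.60,methyl chloride carbon
C-(C)(Cd)(H)2,-4.76,allylic methylene
C-(Cd)2(H)2,-4.29,doubly allylic methylene
C-(C)(CB)(H)2,-4.86,benzylic methylene
C-(C)(CO)(H)2,-5.20,methylene alpha to carbonyl
C-(C)(O)(H)2,-8.10,methylene bearing O
C-(CB)(O)(H)2,-8.10,benzylic methylene bearing O
C-(Cd)(O)(H)2,-8.10,allylic methylene bearing O
C-(C)2(O)(H),-7.20,methine bearing O
C-(C)3(O),-6.60,quaternary bearing O
C-(C)(O)2(H),-16.10,methine with two O
C-(O)2(H)2,-16.10,methylene with two O
C-(C)(N)(H)2,-6.60,methylene bearing N
C-(C)2(N)(H),-5.20,methine bearing N
C-(C)(S)(H)2,-5.65,methylene bearing S
C-(C)(Cl)(H)2,-16.50,methylene bearing Cl
C-(C)2(Cl)(H),-14.80,methine bearing Cl
C-(C)2(CO)(H),-1.70,methine alpha to carbonyl
Cd-(H)2,6.26,terminal =CH2
Cd-(C)(H),8.59,=CH- with alkyl
Cd-(C)2,10.34,disubstituted sp2 carbon
Cd-(Cd)(H),6.78,conjugated =CH-
Cd-(Cd)(C),8.88,conjugated substituted sp2
Cd-(CB)(H),6.78,styrenic =CH-
Cd-(CB)(C),8.64,styrenic substituted sp2
Cd-(O)(H),8.60,enol ether / enol =CH-
Cd-(Cl)(H),-1.20,vinyl chloride carbon
CB-(H),3.30,aromatic CH
CB-(C),5.51,aromatic C with alkyl
CB-(Cd),5.68,aromatic C with vinyl
CB-(CB),4.96,aromatic C biaryl link
CB-(CO),3.70,aromatic C with carbonyl
CB-(O),-0.90,aromatic C with O substituent
CB-(N),-0.50,aromatic C with N substituent
CB-(S),-1.80,aromatic C with S substituent
CB-(Cl),-3.80,aromatic C with Cl
CO-(H)2,-26.00,formaldehyde carbonyl
CO-(C)(H),-29.10,aldehyde carbonyl
CO-(C)2,-31.40,ketone carbonyl
CO-(CB)(H),-29.10,aryl aldehyde carbonyl
CO-(CB)(C),-30.90,aryl ketone carbonyl
CO-(O)(H),-32.10,formate/acid carbonyl with H
CO-(O)(C),-35.10,acid/ester carbonyl
CO-(O)(CB),-36.60,aryl acid/ester carbonyl
CO-(N)(H),-29.60,formamide carbonyl
CO-(N)(C),-32.80,amide carbonyl
O-(C)(H),-37.90,alcohol oxygen
O-(Cd)(H),-37.90,enol oxygen
O-(CB)(H),-37.90,phenol oxygen
O-(C)2,-23.20,ether oxygen
O-(CB)(C),-23.00,aryl alkyl ether oxygen
O-(Cd)(C),-30.50,vinyl ether oxygen
O-(CO)(H),-58.10,carboxylic acid OH
O-(CO)(C),-43.10,ester oxygen
O-(CO)(CB),-40.00,aryl ester oxygen
N-(C)(H)2,4.80,primary amine nitrogen
N-(C)2(H),15.40,secondary amine nitrogen
N-(C)3,24.40,tertiary amine nitrogen
N-(CB)(H)2,4.80,aryl amine nitrogen
N-(CO)(H)2,-14.90,primary amide nitrogen
N-(CO)(C)(H),-4.40,secondary amide nitrogen
S-(C)(H),4.62,thiol sulfur
S-(C)2,11.51,sulfide sulfur
S-(CB)(H),11.96,thiophenol sulfur
S-(CB)(C),11.96,aryl sulfide sulfur
ring:3,27.60,cyclopropane strain
ring:4,26.20,cyclobutane strain
ring:5,6.30,cyclopentane strain
mol:[H][H],0.00,reference state
mol:O=O,0.00,reference state
mol:N#N,0.00,reference state
mol:ClCl,0.00,reference state
mol:O,-57.80,water
mol:Cl,-22.06,hydrogen chloride
mol:[C-]#[O+],-26.42,carbon monoxide
mol:O=C=O,-94.05,carbon dioxide
mol:N,-10.98,ammonia
mol:S,-4.90,hydrogen sulfide
mol:OO,-32.53,hydrogen peroxide
mol:C,-17.83,methane
mol:CO,-48.00,methanol
mol:C=O,-26.00,formaldehyde
mol:O=CO,-90.50,formic acid
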