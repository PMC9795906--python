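# Default country -> area(s) lookup for the nine-area scheme.
# Countries spanning several areas map to a list and are therefore
# "ambiguous": the cascade falls through to coordinates for them.
# Fully user-overridable; codes: And Andes, CAm Central America/Caribbean,
# Pat Patagonia, TSA tropical South America, Afr Afrotropics,
# Aus Australasia+Oceania, Ind Indomalaya, Nea Nearctic, Pal Palaearctic.
Belize: [CAm]
Brazil: [TSA]
British Virgin Islands: [CAm]
Chile: [And, Pat]
Colombia: [And, TSA]
Costa Rica: [CAm]
Cuba: [CAm]
Ecuador: [And, TSA]
French Guiana: [TSA]
Guadeloupe: [CAm]
Guatemala: [CAm]
Guyana: [TSA]
Honduras: [CAm]
Martinique: [CAm]
Nicaragua: [CAm]
Panama: [CAm]
Peru: [And, TSA]
Puerto Rico: [CAm]
Suriname: [TSA]
Venezuela: [And, TSA]
Argentina: [And, Pat]
Bolivia: [And, TSA]
Mexico: [Nea, CAm]
United States: [Nea]
USA: [Nea]
Canada: [Nea]
Cameroon: [Afr]
Democratic Republic of the Congo: [Afr]
Gabon: [Afr]
Guinea: [Afr]
Kenya: [Afr]
Madagascar: [Afr]
Tanzania: [Afr]
Zambia: [Afr]
Australia: [Aus]
New Caledonia: [Aus]
New Zealand: [Aus]
Papua New Guinea: [Aus]
India: [Ind]
Indonesia: [Ind]
Malaysia: [Ind]
Sri Lanka: [Ind]
Thailand: [Ind]
Vietnam: [Ind]
Austria: [Pal]
Belgium: [Pal]
China: [Pal, Ind]
Denmark: [Pal]
Estonia: [Pal]
Finland: [Pal]
France: [Pal]
Germany: [Pal]
Italy: [Pal]
Japan: [Pal]
Netherlands: [Pal]
Norway: [Pal]
Poland: [Pal]
Russia: [Pal]
Spain: [Pal]
Sweden: [Pal]
Switzerland: [Pal]
United Kingdom: [Pal]
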