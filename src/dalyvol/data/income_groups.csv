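location,income_class
Afghanistan,low
Benin,low
Burkina Faso,low
Burundi,low
Central African Republic,low
Chad,low
Comoros,low
Democratic Republic of Congo,low
Eritrea,low
Ethiopia,low
Guinea,low
Guinea-Bissau,low
Haiti,low
Liberia,low
Madagascar,low
Malawi,low
Mali,low
Mozambique,low
Nepal,low
Niger,low
North Korea,low
Rwanda,low
Senegal,low
Sierra Leone,low
Somalia,low
South Sudan,low
Tanzania,low
The Gambia,low
Togo,low
Uganda,low
Zimbabwe,low
Andorra,high
Antigua and Barbuda,high
Australia,high
Austria,high
Bahrain,high
Barbados,high
Belgium,high
Bermuda,high
Brunei,high
Canada,high
Chile,high
Cyprus,high
Czech Republic,high
Denmark,high
Estonia,high
Finland,high
France,high
Germany,high
Greece,high
Greenland,high
Guam,high
Hungary,high
Iceland,high
Ireland,high
Israel,high
Italy,high
Japan,high
Kuwait,high
Latvia,high
Lithuania,high
Luxembourg,high
Malta,high
Netherlands,high
New Zealand,high
Northern Mariana Islands,high
Norway,high
Oman,high
Poland,high
Portugal,high
Puerto Rico,high
Qatar,high
Saudi Arabia,high
Seychelles,high
Singapore,high
Slovakia,high
Slovenia,high
South Korea,high
Spain,high
Sweden,high
Switzerland,high
Taiwan,high
The Bahamas,high
Trinidad and Tobago,high
United Arab Emirates,high
United Kingdom,high
United States,high
Uruguay,high
Virgin Islands,high
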